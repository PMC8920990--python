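"""PMMR normalisation, counts tables and group-comparison statistics.

Counts are normalised to reads per million mapped reads (PMMR),
``1e6 * count / total_mapped``, where ``total_mapped`` is the number of
CCA-trimmed reads with a reported alignment in that library (the most
literal reading of "mapped reads"; a tRNA-assigned-only denominator is
available via ``denominator="trna"``).

Statistics operate on per-replicate proportions or PMMR values (small-n
replicate designs), untransformed:

* ``two_group``   — equal-variance unpaired Student's t,
* ``vs_control``  — one-way ANOVA, then Dunnett-adjusted comparisons of each
  treatment against the designated control (multivariate-t formulation, via
  scipy),
* ``all_pairs``   — Tukey-Kramer adjusted pairwise comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "pmmr",
    "build_counts_table",
    "compare_groups",
    "write_report",
    "StatResult",
    "dunnett_critical_value",
    "null_ttest_rejection_rate",
    "null_dunnett_rejection_rate",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class StatResult:
    method: str          # anova | dunnett | tukey_kramer | t_test
    comparison: str
    statistic: float
    p_value: float
    adjusted: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def pmmr(count: int, total_mapped: int) -> float:
    """Reads per million mapped reads: 1e6 * count / total_mapped."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e6 * count / total_mapped


def build_counts_table(
    tallies: pd.DataFrame,
    total_mapped: dict[tuple[str, int], int],
    level: str = "group",
) -> pd.DataFrame:
    """Derive proportions and PMMR columns from stacked per-library tallies.

    ``tallies`` is a concatenation of :func:`trnaterm.profiler.tally` frames;
    ``total_mapped`` maps (condition, replicate) -> mapped-read denominator.
    Rows with ``n_total == 0`` carry null percentages (not zeros).  Duplicate
    (condition, replicate, key) rows are an error.
    """
    df = tallies[tallies["level"] == level].copy()
    if df.duplicated(subset=["condition", "replicate", "key"]).any():
        raise ValueError("replicate/condition label collision in tallies")
    missing = {(c, r) for c, r in zip(df["condition"], df["replicate"])} - set(
        total_mapped
    )
    if missing:
        raise ValueError(f"no total_mapped for libraries: {sorted(missing)}")
    tm = df.apply(lambda r: total_mapped[(r["condition"], r["replicate"])], axis=1)
    df["total_mapped"] = tm.astype(int)
    nt = df["n_total"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pct_cca"] = np.where(nt > 0, 100.0 * df["n_cca_added"] / nt, np.nan)
        df["pct_cc"] = np.where(nt > 0, 100.0 * df["n_cc_terminating"] / nt, np.nan)
        df["pct_other"] = np.where(nt > 0, 100.0 * df["n_other"] / nt, np.nan)
    for src, dst in (("n_cca_added", "pmmr_cca_added"),
                     ("n_cc_terminating", "pmmr_cc_terminating"),
                     ("n_total", "pmmr_total")):
        df[dst] = [pmmr(int(c), int(t)) for c, t in zip(df[src], df["total_mapped"])]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _validate(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in clean.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    if all(np.var(v) == 0.0 for v in clean.values()):
        raise ValueError("zero within-group variance everywhere; tests are degenerate")
    return clean


def compare_groups(
    groups: dict[str, "np.ndarray | list[float]"],
    design: str,
    control: str | None = None,
    rng: int | np.random.Generator | None = 0,
) -> list[StatResult]:
    """Apply the design-appropriate test(s) to per-replicate values.

    ``design``: ``two_group`` (exactly two groups, Student's t),
    ``vs_control`` (one-way ANOVA + Dunnett against ``control``), or
    ``all_pairs`` (Tukey-Kramer).  ``rng`` seeds the multivariate-t
    integration inside Dunnett so results are reproducible.
    """
    clean = _validate(groups)
    names = list(clean)
    results: list[StatResult] = []
    if design == "two_group":
        if len(names) != 2:
            raise ValueError("two_group design needs exactly 2 groups")
        t, p = sps.ttest_ind(clean[names[0]], clean[names[1]], equal_var=True)
        return [StatResult("t_test", f"{names[0]} vs {names[1]}",
                           float(t), float(p), adjusted=False)]
    if design == "vs_control":
        if control is None or control not in clean:
            raise ValueError("vs_control design needs a control group name")
        f, p = sps.f_oneway(*clean.values())
        results.append(StatResult("anova", "between-groups", float(f), float(p),
                                  adjusted=False))
        treatments = [n for n in names if n != control]
        res = sps.dunnett(*(clean[n] for n in treatments),
                          control=clean[control], rng=rng)
        for name, stat, pv in zip(treatments, np.atleast_1d(res.statistic),
                                  np.atleast_1d(res.pvalue)):
            results.append(StatResult("dunnett", f"{name} vs {control}",
                                      float(stat), float(pv), adjusted=True))
        return results
    if design == "all_pairs":
        res = sps.tukey_hsd(*clean.values())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                results.append(
                    StatResult("tukey_kramer", f"{names[i]} vs {names[j]}",
                               float(res.statistic[i, j]),
                               float(res.pvalue[i, j]), adjusted=True)
                )
        return results
    raise ValueError(f"unknown design {design!r}")


def dunnett_critical_value(n_treatment: int, n_per_group: int,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Two-sided Dunnett critical value for a balanced design.

    ``n_treatment`` treatment groups of ``n_per_group`` observations each
    plus an equal-size control.  Computed from the multivariate-t rectangle
    probability P(max_i |T_i| <= c) = 1 - alpha with the equicorrelated
    rho = 0.5 structure of balanced designs.  Used by the Monte-Carlo
    calibration of the null rejection rate; accuracy is limited by the QMC
    integration of the multivariate t (~1e-3 on the probability).
    """
    k = n_treatment
    df = (k + 1) * (n_per_group - 1)
    corr = np.full((k, k), 0.5)
    np.fill_diagonal(corr, 1.0)
    mvt = sps.multivariate_t(shape=corr, df=df)

    def coverage(c: float) -> float:
        # fixed QMC seed per evaluation keeps the objective smooth in c
        return float(
            mvt.cdf(np.full(k, c), lower_limit=np.full(k, -c),
                    random_state=np.random.default_rng(seed))
        )

    return float(optimize.brentq(lambda c: coverage(c) - (1 - alpha), 1.0, 10.0,
                                 xtol=1e-4))


def _pooled_t_stats(groups: np.ndarray) -> np.ndarray:
    """Vectorised treatment-vs-first-group t statistics with pooled variance.

    ``groups`` has shape (n_sim, k, n); returns (n_sim, k-1).
    """
    n_sim, k, n = groups.shape
    means = groups.mean(axis=2)
    ss = ((groups - means[:, :, None]) ** 2).sum(axis=2)
    sp2 = ss.sum(axis=1) / (k * (n - 1))
    denom = np.sqrt(sp2 * 2.0 / n)
    return (means[:, 1:] - means[:, [0]]) / denom[:, None]


def null_ttest_rejection_rate(n_sim: int, n_per_group: int = 3,
                              alpha: float = 0.05,
                              rng: np.random.Generator | int = 0) -> float:
    """Empirical type-I error of the equal-variance two-sample t-test under a
    simulated global null (vectorised Monte Carlo)."""
    gen = np.random.default_rng(rng)
    g = gen.standard_normal((n_sim, 2, n_per_group))
    t = _pooled_t_stats(g)[:, 0]
    crit = sps.t.ppf(1 - alpha / 2, df=2 * (n_per_group - 1))
    return float(np.mean(np.abs(t) > crit))


def null_dunnett_rejection_rate(n_sim: int, n_treatment: int = 2,
                                n_per_group: int = 3, alpha: float = 0.05,
                                rng: np.random.Generator | int = 0) -> float:
    """Empirical family-wise type-I error of the two-sided Dunnett procedure
    under a simulated global null: reject when max |T_i| exceeds the
    multivariate-t critical value."""
    gen = np.random.default_rng(rng)
    g = gen.standard_normal((n_sim, n_treatment + 1, n_per_group))
    t = _pooled_t_stats(g)
    crit = dunnett_critical_value(n_treatment, n_per_group, alpha=alpha)
    return float(np.mean(np.max(np.abs(t), axis=1) > crit))


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def write_report(counts_table: pd.DataFrame, stat_results: list[StatResult],
                 outdir) -> dict[str, str]:
    """Write TSV tables plus a JSON summary; returns the paths written.

    The JSON carries pie-chart-ready per-condition percentage triples
    (mean across replicates of pct_cca / pct_cc / pct_other per group),
    the PMMR table and the serialised statistics, under a versioned schema.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(str(outdir), "counts.tsv"),
        "stats": os.path.join(str(outdir), "stats.tsv"),
        "summary": os.path.join(str(outdir), "summary.json"),
    }
    counts_table.to_csv(paths["counts"], sep="\t", index=False)
    stats_df = pd.DataFrame([asdict(r) for r in stat_results])
    stats_df.to_csv(paths["stats"], sep="\t", index=False)

    pies: dict[str, dict[str, dict[str, float]]] = {}
    for (cond, key), sub in counts_table.groupby(["condition", "key"]):
        triple = {
            "pct_cca": float(np.nanmean(sub["pct_cca"])),
            "pct_cc": float(np.nanmean(sub["pct_cc"])),
            "pct_other": float(np.nanmean(sub["pct_other"])),
        }
        if not np.isnan(triple["pct_cca"]):
            pies.setdefault(cond, {})[key] = triple
    summary = {
        "schema_version": SCHEMA_VERSION,
        "percent_triples": pies,
        "pmmr": counts_table[
            ["condition", "replicate", "key", "pmmr_cca_added",
             "pmmr_cc_terminating", "pmmr_total"]
        ].to_dict(orient="records"),
        "stat_results": [asdict(r) for r in stat_results],
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2)
    return paths
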