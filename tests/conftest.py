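import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_reference():
    """Small simulated genome + catalog shared across tests (12 genes:
    2 ending CCA, 1 ending CC, 9 OTHER, one flagged mito)."""
    from trnaterm.simulate import generate_reference

    refs, catalog = generate_reference(
        n_genes=12, n_cca_ending=2, n_cc_ending=1, gene_len=72,
        genome_len=20_000, seed=11, n_mito=1,
    )
    return refs, catalog


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Plain DP edit distance (oracle; independent of the package)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def adapter_oracle(read: str, adapter: str, max_error_rate: float = 0.1,
                   min_overlap: int = 3) -> int:
    """Exhaustive semi-global adapter search; returns the cut position or -1.

    Enumerates every start s and every matched adapter length: the full
    adapter against every read substring starting at s, and adapter prefixes
    against the read suffix (occurrence running off the 3' end).  Accepts
    occurrences with errors <= floor(rate * matched_len) and matched_len >=
    min_overlap; picks max(matched_len - 2*errors), ties -> leftmost s.
    """
    n, m = len(read), len(adapter)
    best = None  # (score, s)
    def consider(s, j, e):
        nonlocal best
        if j < min_overlap or e > int(max_error_rate * j):
            return
        cand = (j - 2 * e, -s)
        if best is None or cand > best:
            best = cand
    for s in range(n + 1):
        e_full = min(levenshtein(adapter, read[s:s + k]) for k in range(n - s + 1))
        consider(s, m, e_full)
        for j in range(min_overlap, m):
            consider(s, j, levenshtein(adapter[:j], read[s:]))
    return -best[1] if best is not None else -1


COMP = str.maketrans("ACGT", "TGCA")


def exhaustive_align(seq: str, references: dict[str, str], max_mismatch: int = 3):
    """Brute-force scan of every ungapped end-to-end placement on both
    strands.  Returns (min_mismatch, [(ref, pos, strand), ...]) or None."""
    m = len(seq)
    best, placements = max_mismatch + 1, []
    for name, ref in references.items():
        for s, strand in ((seq, "+"), (seq.translate(COMP)[::-1], "-")):
            arr_r = np.frombuffer(s.encode(), dtype=np.uint8)
            arr_g = np.frombuffer(ref.upper().encode(), dtype=np.uint8)
            for pos in range(len(ref) - m + 1):
                nm = int(np.count_nonzero(arr_g[pos:pos + m] != arr_r))
                if nm < best:
                    best, placements = nm, [(name, pos, strand)]
                elif nm == best:
                    placements.append((name, pos, strand))
    if best > max_mismatch:
        return None
    return best, placements


@pytest.fixture(scope="session")
def oracles():
    return {
        "levenshtein": levenshtein,
        "adapter": adapter_oracle,
        "align": exhaustive_align,
    }
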