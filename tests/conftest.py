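import numpy as np
import pytest

from neotrack.clusters import load_builtin_cluster_db
from neotrack.repertoire import AA_ALPHABET, Clonotype, Repertoire, recompute_frequencies


def wagner_fischer(a: str, b: str) -> int:
    """Full, uncapped Levenshtein dynamic program — the reference oracle.

    Deliberately naive: complete (len(a)+1) x (len(b)+1) table, no band,
    no early exit, so it shares no code path with the implementation.
    """
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        dp[i][0] = i
    for j in range(lb + 1):
        dp[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            dp[i][j] = min(dp[i - 1][j] + 1, dp[i][j - 1] + 1,
                           dp[i - 1][j - 1] + cost)
    return dp[la][lb]


def random_aa_string(rng: np.random.Generator, lo: int = 8, hi: int = 20) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AA_ALPHABET), n))


def make_repertoire(counts: dict[str, int], sample_id: str = "s1",
                    v_call: str = "TRBV13-1", **meta) -> Repertoire:
    clons = [Clonotype(cdr3_aa=c, v_call=v_call, count=n)
             for c, n in counts.items()]
    return recompute_frequencies(
        Repertoire(sample_id=sample_id, clonotypes=clons, **meta))


@pytest.fixture(scope="session")
def builtin_db():
    return load_builtin_cluster_db()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def airr_file(tmp_path):
    def _write(rows, name="sample.tsv"):
        path = tmp_path / name
        header = "junction_aa\tv_call\tj_call\tduplicate_count\n"
        body = "".join(
            f"{r[0]}\t{r[1]}\t{r[2] if len(r) > 3 else 'TRBJ2-1'}\t{r[-1]}\n"
            for r in rows
        )
        path.write_text(header + body)
        return path

    return _write
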