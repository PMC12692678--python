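"""Independent reference implementations used only to cross-check the package.

Kept deliberately naive and separate from the library code paths.
"""

from functools import lru_cache


def recursive_alignment_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Maximal global-alignment score by direct recursion over the recurrence."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append((match if a[i] == b[j] else mismatch) + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def enumerate_alignment_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Exhaustive enumeration of every global alignment (tiny inputs only)."""
    best = [float("-inf")]

    def walk(i: int, j: int, acc: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, acc + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            walk(i + 1, j, acc + gap)
        if j < len(b):
            walk(i, j + 1, acc + gap)

    walk(0, 0, 0.0)
    return best[0]


def brute_force_top_genes(summaries, n: int) -> list[str]:
    """Full sort by rank-normalised |mean_logfc| + |gene_div|, ties by gene id."""
    import scipy.stats

    aml = summaries["mean_logfc"].abs().to_numpy()
    agd = summaries["gene_div"].abs().to_numpy()
    score = scipy.stats.rankdata(aml) / len(aml) + scipy.stats.rankdata(agd) / len(agd)
    ranked = sorted(zip(-score, summaries["gene_id"]))
    return [g for _, g in ranked[:n]]
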