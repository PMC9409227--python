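import numpy as np
import pytest

from segain.genomic_io import GenomicInterval, Peak
from segain.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down generator config for fast unit tests."""
    return SyntheticConfig(
        genome=(("chr1", 2_000_000), ("chr2", 2_000_000)),
        n_background_peaks=90,
        n_planted_se=4,
        shared_gain=2,
        line_specific_gain=1,
        n_fragments=20_000,
        n_tumor=60,
        n_normal=12,
        planted_genes=2,
        seed=11,
    )


def random_peaks(rng, n, span=200_000, max_len=3_000, chroms=("chr1",)):
    peaks = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        peaks.append(Peak(GenomicInterval(chrom, start, start + length), name=f"p{i}"))
    return peaks


def stitch_oracle(peaks, stitch_distance):
    """Brute-force transitive closure of the pairwise gap-< relation.

    Two peaks are related when they share a chromosome and the gap between
    them (0 if overlapping) is < stitch_distance; regions are the
    connected components, returned as sorted hull tuples with member sets.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i].interval, peaks[j].interval
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap < stitch_distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        ivs = [peaks[i].interval for i in members]
        out.append((
            ivs[0].chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            frozenset(members),
        ))
    return sorted(out)


def brute_force_coverage(spans, chrom_len, bin_size):
    """Per-base coverage accumulated into bins, the slow way."""
    base = np.zeros(chrom_len)
    for s, e in spans:
        base[s:e] += 1
    n_bins = -(-chrom_len // bin_size)
    padded = np.zeros(n_bins * bin_size)
    padded[:chrom_len] = base
    return padded.reshape(n_bins, bin_size).sum(axis=1)


def bh_closed_form(pvals):
    """Step-up BH: q_(i) = min_{j>=i} ( p_(j) * n / j ), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
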