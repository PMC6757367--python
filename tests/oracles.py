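"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: inbreeding by Wright's
path-counting sum over inbreeding loops, ROH by exhaustive enumeration of
all (start, end) SNP pairs, and L_auto by explicit partition at oversized
gaps.  They are exponential/quadratic and only run on tiny inputs.
"""

from __future__ import annotations

import numpy as np


def wright_inbreeding(sire: dict, dam: dict) -> dict:
    """F by summing (1/2)^(n+1) (1+F_A) over all inbreeding loops.

    ``sire``/``dam`` map id -> parent id or None.  A loop is a pair of
    ascending paths from the sire and the dam meeting only at their common
    ancestor A; n is the total number of links in the loop.
    """

    def paths_up(x):
        out = [(x,)]
        for p in (sire[x], dam[x]):
            if p is not None:
                out += [(x,) + t for t in paths_up(p)]
        return out

    memo: dict = {}

    def f_of(x):
        if x in memo:
            return memo[x]
        s, d = sire[x], dam[x]
        if s is None or d is None:
            memo[x] = 0.0
            return 0.0
        total = 0.0
        for p1 in paths_up(s):
            for p2 in paths_up(d):
                if p1[-1] != p2[-1]:
                    continue
                if set(p1[:-1]) & set(p2[:-1]):
                    continue
                n_links = (len(p1) - 1) + (len(p2) - 1)
                total += 0.5 ** (n_links + 1) * (1.0 + f_of(p1[-1]))
        memo[x] = total
        return total

    return {x: f_of(x) for x in sire}


def exhaustive_roh(geno_row: np.ndarray, bp: np.ndarray, params) -> list[tuple[int, int]]:
    """All maximal (start, end) SNP index pairs that are fully homozygous
    with no internal gap over the limit, then size/density-filtered."""
    hom = (geno_row == 0) | (geno_row == 2)
    n = len(bp)
    valid: set[tuple[int, int]] = set()
    for s in range(n):
        if not hom[s]:
            continue
        max_gap = 0
        for e in range(s, n):
            if not hom[e]:
                break
            if e > s:
                max_gap = max(max_gap, int(bp[e] - bp[e - 1]))
            if max_gap > params.max_gap_bp:
                break
            valid.add((s, e))
    out = []
    for (s, e) in valid:
        if (s - 1, e) in valid or (s, e + 1) in valid:
            continue
        n_snps = e - s + 1
        length = int(bp[e] - bp[s] + 1)
        if (
            n_snps >= params.min_snps
            and length >= params.min_length_bp
            and length / n_snps <= params.density_bp_per_snp
        ):
            out.append((s, e))
    return sorted(out)


def partition_L_auto(bp: np.ndarray, max_gap_bp: float) -> int:
    """Split the map at gaps > max_gap_bp; sum the spans of the pieces."""
    segments = []
    start = 0
    for k in range(1, len(bp)):
        if bp[k] - bp[k - 1] > max_gap_bp:
            segments.append((start, k - 1))
            start = k
    segments.append((start, len(bp) - 1))
    return int(sum(bp[e] - bp[s] for s, e in segments))


def random_pedigree(rng: np.random.Generator, n: int) -> list[tuple]:
    """Random acyclic pedigree records (id, sire, dam) over n individuals.

    Early individuals are founders; later ones draw parents among their
    predecessors, sometimes sharing or missing one, which produces a rich
    mix of inbreeding loops.
    """
    records = []
    n_founders = max(2, int(rng.integers(2, max(3, n // 3))))
    for i in range(n):
        if i < n_founders or rng.random() < 0.1:
            records.append((f"I{i}", None, None))
            continue
        s = f"I{rng.integers(0, i)}"
        d = f"I{rng.integers(0, i)}"
        if rng.random() < 0.05:
            d = None  # one unknown parent
        records.append((f"I{i}", s, d))
    return records


def random_panel_arrays(
    rng: np.random.Generator,
    n_ind: int,
    n_snps: int,
    hom_prob: float = 0.42,
    missing_prob: float = 0.03,
):
    """(genotypes, positions) with run-friendly genotype frequencies and
    gap sizes straddling the 150 kb split threshold."""
    probs = [hom_prob, 1 - 2 * hom_prob - missing_prob, hom_prob, missing_prob]
    geno = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8), size=(n_ind, n_snps), p=probs
    )
    gaps = rng.integers(20_000, 190_000, size=n_snps)
    bp = np.cumsum(gaps)
    return geno, bp.astype(np.int64)
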