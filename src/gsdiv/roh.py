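"""Runs of homozygosity: genotype I/O, QC, detection, and F_ROH summaries.

A run of homozygosity (ROH) is a contiguous stretch of homozygous SNP calls
interpreted as an autozygous segment — both chromosomes inherited from a
common ancestor.  The genomic inbreeding coefficient is

    F_ROH(i) = sum of ROH lengths of individual i / L_auto,

where L_auto is the length of the autosomal genome on which ROH can be
detected: SNP-covered span after withholding inter-SNP gaps longer than the
gap limit (150 kb by default).

Detection criteria follow the common 50K-chip convention: a run must hold at
least 15 SNPs AND span at least 1000 kb, keep at least one SNP per 75 kb,
and never jump a gap of more than 150 kb between consecutive SNPs.  Two
scan modes are provided:

* ``strict`` — maximal runs of homozygous non-missing calls (missing breaks
  a run), split at oversized gaps, then size/density-filtered.  This mode
  admits an exact exhaustive-enumeration oracle and is used for validation.
* ``windowed`` — the sliding-window heuristic of the usual scanners: a
  window of 15 SNPs is "homozygous" if it has at most 1 heterozygote and 5
  missing calls; a SNP is candidate-included when the fraction of
  homozygous windows covering it reaches the hit threshold (0.05).

Genotypes are exchanged in PLINK 1 bed/bim/fam (v1.00, SNP-major); the
2-bit codec is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: default autosome count retained for ROH (bovine-like); chromosomes whose
#: label is non-numeric or exceeds this are treated as non-autosomal.
MAX_AUTOSOME = 29


@dataclass(frozen=True)
class RohParams:
    """Detection thresholds (kb units mirror the usual scanner flags)."""

    min_snps: int = 15
    min_length_kb: float = 1000.0
    window_snps: int = 15
    density_kb_per_snp: float = 75.0
    max_gap_kb: float = 150.0
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05
    mode: str = "windowed"

    @property
    def min_length_bp(self) -> float:
        return self.min_length_kb * 1000.0

    @property
    def max_gap_bp(self) -> float:
        return self.max_gap_kb * 1000.0

    @property
    def density_bp_per_snp(self) -> float:
        return self.density_kb_per_snp * 1000.0


@dataclass
class GenotypePanel:
    """Individuals x SNPs genotype matrix with its SNP map.

    ``genotypes`` holds counts of the first (bim A1) allele: 0/1/2, with
    ``MISSING`` (-1) for no-calls.  ``snp_map`` columns: chrom, snp_id,
    bp, cM.
    """

    ids: list[str]
    genotypes: np.ndarray  # int8, shape (n_individuals, n_snps)
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} inconsistent with "
                f"{len(self.ids)} individuals x {len(self.snp_map)} SNPs"
            )
        vals = np.unique(self.genotypes)
        bad = set(vals.tolist()) - {-1, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if not np.all(np.diff(bp) > 0):
                raise ValueError(
                    f"SNP positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)


@dataclass(frozen=True)
class RohSegment:
    """One autozygous run, 1-based inclusive physical coordinates."""

    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    """Segment list as a .hom-style table (IID, CHR, POS1, POS2, KB, NSNP)."""
    return pd.DataFrame(
        {
            "IID": [s.individual for s in segments],
            "CHR": [s.chrom for s in segments],
            "POS1": [s.start_bp for s in segments],
            "POS2": [s.end_bp for s in segments],
            "KB": [s.length_kb for s in segments],
            "NSNP": [s.n_snps for s in segments],
        }
    )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam I/O
# ---------------------------------------------------------------------------

# 2-bit codes in a .bed byte, per genotype: 00 hom A1, 10 het, 11 hom A2,
# 01 missing.  We count A1 alleles: 0b00 -> 2, 0b10 -> 1, 0b11 -> 0.
_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix) -> GenotypePanel:
    """Read a bed/bim/fam triple (bed v1.00, SNP-major layout)."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    if fam.duplicated(["fid", "iid"]).any():
        dup = fam[fam.duplicated(["fid", "iid"])].iloc[0]
        raise ValueError(f"duplicate individual in .fam: {dup.fid}/{dup.iid}")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cM", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "cM": float, "bp": np.int64},
    )
    n_ind, n_snp = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            f"{prefix}.bed: bad magic bytes {raw[:3].hex()} "
            "(expected v1.00 SNP-major bed)"
        )
    bytes_per_snp = (n_ind + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * n_snp:
        raise ValueError(
            f"{prefix}.bed payload is {payload.size} bytes; expected "
            f"{bytes_per_snp * n_snp} for {n_ind} individuals x {n_snp} SNPs"
        )
    mat = payload.reshape(n_snp, bytes_per_snp)
    # unpack 4 genotypes per byte, little-end-first within the byte
    codes = np.stack(
        [(mat >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(n_snp, bytes_per_snp * 4)[:, :n_ind]
    geno = _DECODE[codes].T.copy()  # (n_ind, n_snp)
    snp_map = bim[["chrom", "snp_id", "bp", "cM"]].copy()
    return GenotypePanel(list(fam["iid"]), geno, snp_map)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a GenotypePanel as bed/bim/fam (bed v1.00, SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_ind, n_snp = panel.n_individuals, panel.n_snps
    fam = pd.DataFrame(
        {
            "fid": panel.ids,
            "iid": panel.ids,
            "father": "0",
            "mother": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": panel.snp_map["chrom"],
            "snp_id": panel.snp_map["snp_id"],
            "cM": panel.snp_map["cM"],
            "bp": panel.snp_map["bp"],
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    lut = np.empty(4, dtype=np.uint8)
    for g, code in _ENCODE.items():
        lut[g if g != MISSING else 3] = code
    g = panel.genotypes.T  # (n_snp, n_ind)
    codes = lut[np.where(g == MISSING, 3, g)]
    bytes_per_snp = (n_ind + 3) // 4
    padded = np.zeros((n_snp, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_ind] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    n_snps_in: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_snps_out: int
    n_individuals_in: int
    n_removed_individuals: int
    n_individuals_out: int


def qc_filter(
    panel: GenotypePanel,
    min_snp_call_rate: float = 0.95,
    min_maf: float = 0.01,
    min_ind_call_rate: float = 0.95,
) -> tuple[GenotypePanel, QcReport]:
    """Remove low-call-rate SNPs, then low-MAF SNPs, then low-call individuals.

    A SNP is dropped when genotyped in fewer than ``min_snp_call_rate`` of
    individuals, or when its minor allele frequency (computed on the
    non-missing calls of surviving SNPs) is strictly below ``min_maf``.
    """
    g = panel.genotypes
    n_ind, n_snp = g.shape
    if n_snp == 0 or n_ind == 0:
        raise ValueError("empty genotype panel")
    called = g != MISSING
    snp_call_rate = called.mean(axis=0)
    keep_cr = snp_call_rate >= min_snp_call_rate
    n_cr = int((~keep_cr).sum())

    with np.errstate(invalid="ignore"):
        af = np.where(
            called.sum(axis=0) > 0,
            np.where(g == MISSING, 0, g).sum(axis=0) / (2.0 * called.sum(axis=0)),
            0.0,
        )
    maf = np.minimum(af, 1.0 - af)
    keep_maf = maf >= min_maf
    n_maf = int((keep_cr & ~keep_maf).sum())

    keep_snp = keep_cr & keep_maf
    if not keep_snp.any():
        raise ValueError("QC removed every SNP")
    g2 = g[:, keep_snp]
    ind_call_rate = (g2 != MISSING).mean(axis=1)
    keep_ind = ind_call_rate >= min_ind_call_rate
    n_ind_rm = int((~keep_ind).sum())

    out = GenotypePanel(
        [iid for iid, k in zip(panel.ids, keep_ind) if k],
        g2[keep_ind].copy(),
        panel.snp_map.loc[keep_snp].reset_index(drop=True),
    )
    report = QcReport(
        n_snps_in=n_snp,
        n_removed_call_rate=n_cr,
        n_removed_maf=n_maf,
        n_snps_out=out.n_snps,
        n_individuals_in=n_ind,
        n_removed_individuals=n_ind_rm,
        n_individuals_out=out.n_individuals,
    )
    return out, report


# ---------------------------------------------------------------------------
# L_auto
# ---------------------------------------------------------------------------

def _is_autosome(label: str) -> bool:
    try:
        return 1 <= int(label) <= MAX_AUTOSOME
    except (TypeError, ValueError):
        return False


def autosomal(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Rows of the map on autosomes (numeric labels 1..MAX_AUTOSOME)."""
    keep = snp_map["chrom"].map(_is_autosome)
    return snp_map.loc[keep]


def compute_L_auto(
    snp_map: pd.DataFrame, max_gap_bp: float = 150_000
) -> tuple[pd.Series, int]:
    """SNP-covered autosomal length after withholding gaps > ``max_gap_bp``.

    Per chromosome: (last - first position) minus the summed sizes of
    inter-SNP gaps exceeding the limit.  Returns (per-chromosome Series,
    total).  A chromosome with < 2 SNPs contributes 0 (warned).
    """
    amap = autosomal(snp_map)
    per_chrom = {}
    for chrom, grp in amap.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy()
        if len(bp) < 2:
            logger.warning(
                "chromosome %s has %d SNP(s); contributes 0 to L_auto",
                chrom, len(bp),
            )
            per_chrom[chrom] = 0
            continue
        gaps = np.diff(bp)
        span = int(bp[-1] - bp[0])
        withheld = int(gaps[gaps > max_gap_bp].sum())
        per_chrom[chrom] = span - withheld
    series = pd.Series(per_chrom, name="L_auto_bp", dtype=np.int64)
    return series, int(series.sum())


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_roh(panel: GenotypePanel, params: RohParams | None = None) -> list[RohSegment]:
    """Detect ROH per individual and autosome under ``params``.

    See module docstring for the two modes.  Emitted segments span the
    physical positions of their first and last SNP and satisfy all four
    run constraints (SNP count, length, density, internal gap).
    """
    params = params or RohParams()
    if params.mode not in ("windowed", "strict"):
        raise ValueError(f"unknown mode: {params.mode!r}")
    amap = autosomal(panel.snp_map)
    segments: list[RohSegment] = []
    for chrom, grp in amap.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        sub = panel.genotypes[:, cols]
        if params.mode == "windowed" and params.window_snps > len(cols):
            logger.warning(
                "chromosome %s has %d SNPs < window of %d; skipped",
                chrom, len(cols), params.window_snps,
            )
            continue
        for i, iid in enumerate(panel.ids):
            geno = sub[i]
            if params.mode == "strict":
                candidate = (geno == 0) | (geno == 2)
            else:
                candidate = _window_candidates(geno, params)
            segments.extend(
                _emit_runs(iid, str(chrom), bp, geno, candidate, params)
            )
    return segments


def _window_candidates(geno: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP candidate flags from the sliding-window homozygosity vote."""
    w = params.window_snps
    n = geno.size
    het = (geno == 1).astype(np.int32)
    mis = (geno == MISSING).astype(np.int32)
    # windowed counts via cumulative sums; window j covers SNPs [j, j+w)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - w + 1
    het_in = chet[w:] - chet[:-w]
    mis_in = cmis[w:] - cmis[:-w]
    hom_win = (het_in <= params.window_max_het) & (mis_in <= params.window_max_missing)
    # hit rate of SNP k = homozygous fraction of the windows covering it
    hom_cum = np.concatenate([[0], np.cumsum(hom_win.astype(np.int64))])
    first = np.maximum(0, np.arange(n) - w + 1)
    last = np.minimum(np.arange(n), n_win - 1)
    covering = last - first + 1
    hits = hom_cum[last + 1] - hom_cum[first]
    return hits / covering >= params.window_hit_threshold


def _emit_runs(
    iid: str,
    chrom: str,
    bp: np.ndarray,
    geno: np.ndarray,
    candidate: np.ndarray,
    params: RohParams,
) -> list[RohSegment]:
    """Maximal candidate runs, split at oversized gaps, size/density filtered."""
    out: list[RohSegment] = []
    n = candidate.size
    big_gap = np.zeros(n, dtype=bool)
    big_gap[1:] = np.diff(bp) > params.max_gap_bp
    # run breaks where candidacy stops or the gap to the previous SNP is big
    start = None
    for k in range(n + 1):
        boundary = k == n or not candidate[k] or (start is not None and big_gap[k])
        if start is not None and boundary:
            out.extend(_filter_run(iid, chrom, bp, start, k - 1, params))
            start = None
        if k < n and candidate[k] and (start is None):
            start = k
    return out


def _filter_run(
    iid: str, chrom: str, bp: np.ndarray, s: int, e: int, params: RohParams
) -> list[RohSegment]:
    n_snps = e - s + 1
    length = int(bp[e] - bp[s] + 1)
    if (
        n_snps >= params.min_snps
        and length >= params.min_length_bp
        and length / n_snps <= params.density_bp_per_snp
    ):
        return [RohSegment(iid, chrom, int(bp[s]), int(bp[e]), n_snps)]
    return []


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class RohSummary:
    """Per-individual ROH burden and the panel-level detectable length."""

    per_individual: pd.DataFrame  # index id; sum_bp, n_roh, F_ROH, L_ROH_mean_kb
    L_auto_bp: int
    L_auto_per_chrom: pd.Series = field(repr=False, default=None)


def summarize_roh(
    segments: list[RohSegment],
    snp_map: pd.DataFrame,
    max_gap_bp: float = 150_000,
    ids: list[str] | None = None,
) -> RohSummary:
    """F_ROH and mean ROH length per individual.

    ``ids`` fixes the individuals reported (zero rows for segment-free
    individuals, flagged via ``n_roh == 0``); defaults to those appearing
    in ``segments``.
    """
    per_chrom, L_auto = compute_L_auto(snp_map, max_gap_bp)
    if L_auto <= 0:
        raise ValueError("L_auto is zero; cannot form F_ROH")
    if ids is None:
        ids = sorted({s.individual for s in segments})
    sums = {iid: 0 for iid in ids}
    counts = {iid: 0 for iid in ids}
    for seg in segments:
        if seg.individual not in sums:
            continue
        sums[seg.individual] += seg.length_bp
        counts[seg.individual] += 1
    df = pd.DataFrame(
        {
            "sum_bp": [sums[i] for i in ids],
            "n_roh": [counts[i] for i in ids],
        },
        index=pd.Index(ids, name="id"),
    )
    df["F_ROH"] = df["sum_bp"] / L_auto
    df["L_ROH_mean_kb"] = np.where(
        df["n_roh"] > 0, df["sum_bp"] / df["n_roh"].replace(0, 1) / 1000.0, 0.0
    )
    return RohSummary(df, L_auto, per_chrom)


def roh_length_histogram(
    segments: list[RohSegment],
    bin_edges_kb: tuple[float, ...] = (1000, 2000, 4000, 8000, 16000),
) -> pd.DataFrame:
    """Counts of segments per half-open length class [edge_k, edge_{k+1}).

    Rows: individuals; columns: length classes in kb.  Segments outside
    [first, last) edge are not counted.
    """
    edges = np.asarray(bin_edges_kb, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    labels = [
        f"[{edges[k]:g},{edges[k + 1]:g})" for k in range(len(edges) - 1)
    ]
    ids = sorted({s.individual for s in segments})
    counts = pd.DataFrame(
        0, index=pd.Index(ids, name="id"), columns=labels, dtype=np.int64
    )
    for seg in segments:
        b = int(np.searchsorted(edges, seg.length_kb, side="right")) - 1
        if 0 <= b < len(labels):
            counts.loc[seg.individual, labels[b]] += 1
    return counts
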