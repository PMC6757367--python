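"""Synthetic breeding-scheme generator with known ground truth.

Real dairy-bull datasets are proprietary, so every pipeline stage is
exercised on simulated data built to mimic their structure:

* a multi-generation pedigree over birth years 2005-2015 with a regime
  change in 2011 — the switch from progeny-testing selection (PTS: old,
  heavily-used proven sires) to genomic selection (GS: young sires, less
  skewed usage, steeper genetic-merit trend);
* SNP genotypes produced by *gene dropping*: founders carry labelled
  haplotypes, every meiosis recombines them (Haldane model, no
  interference), and the founder-origin labels are propagated alongside
  allele states.  Identity of the two labels at a position is true
  autozygosity, giving an exact per-individual IBD fraction F_true
  against which ROH-based estimates can be validated;
* an index trait built as parental mean + Mendelian-sampling deviate,
  observed with noise scaled so the within-cohort standard deviation is
  about 20 points (the convention for the French total merit index).

All randomness flows from ``SimConfig.seed`` through spawned generator
streams, so every output is reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree
from .roh import GenotypePanel, write_plink

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Breeding-scheme and genome parameters.

    The defaults describe a national-breed-scale scheme: cohorts of ~140
    bulls per year before the 2011 regime change and ~120 after, proven
    sires used at a mean parental age of 70 months before vs 36 months
    after (a generation-interval reduction factor of ~1.9), stronger
    sire-usage skew before the change, and more intense merit selection
    after it.  The desk-scale genome is 5 chromosomes x 100 Mb at 1 cM/Mb
    with chip-like ~62.5 kb marker spacing.
    """

    seed: int = 0
    start_year: int = 2005
    end_year: int = 2015
    regime_change_year: int = 2011
    cohort_size_pre: int = 140
    cohort_size_post: int = 120
    n_founder_males: int = 80
    n_founder_females: int = 160
    founder_year_span: int = 8  # founders born start_year-1-span .. start_year-1
    n_sires_pre: int = 25
    n_sires_post: int = 50
    sire_skew_pre: float = 0.25  # geometric usage weight w_k ~ (1-s)^k
    sire_skew_post: float = 0.05
    mean_parental_age_pre: float = 70.0  # months
    mean_parental_age_post: float = 36.0
    parental_age_sd: float = 6.0  # months; spread of drawn parental ages
    dam_top_frac: float = 0.6
    sel_top_frac_pre: float = 0.30  # sire truncation-selection fraction
    sel_top_frac_post: float = 0.20
    founder_trend_per_year: float = 1.0  # pre-existing genetic trend, points/yr
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    chrom_length_cM: float = 100.0
    snps_per_chromosome: int = 1600
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    founder_ld_blocks: bool = False  # block-copied founder haplotypes (adds LD)
    ld_block_cM: float = 2.0
    n_founder_hap_pool: int = 24  # pool size when founder_ld_blocks is on
    genetic_sd: float = 12.0  # index points
    noise_sd: float = 16.0  # so cohort SD ~ sqrt(12^2+16^2) = 20 points
    gebv_noise_sd: float = 7.0  # genomic-proxy noise: GS accuracy ~ 0.86

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if not (self.start_year < self.regime_change_year <= self.end_year):
            raise ValueError("regime change must fall inside the simulated years")
        for name in (
            "cohort_size_pre", "cohort_size_post", "n_founder_males",
            "n_founder_females", "n_sires_pre", "n_sires_post",
            "n_chromosomes", "snps_per_chromosome",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sire_skew_pre", "sire_skew_post"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.chrom_length_cM <= 0:
            raise ValueError("chromosome genetic length must be positive")
        for name in ("mean_parental_age_pre", "mean_parental_age_post"):
            if getattr(self, name) <= 12.0:
                raise ValueError(f"{name} must exceed 12 months")

    def regime(self, year: int) -> str:
        return "PTS" if year < self.regime_change_year else "GS"


def bovine_preset(**overrides) -> SimConfig:
    """A bovine-like genome: 29 autosomes x ~85 Mb, same scheme defaults."""
    base = dict(
        n_chromosomes=29,
        chrom_length_bp=85_000_000,
        chrom_length_cM=85.0,
        snps_per_chromosome=1360,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# breeding-scheme pedigree + index
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Joint output of the breeding-scheme simulation."""

    pedigree: Pedigree
    contributions: pd.DataFrame  # id, offspring, group, birth_year (sires)
    index: pd.Series  # observed merit index per id
    breeding_value: pd.Series
    sex: pd.Series  # 'M'/'F'


def simulate_scheme(cfg: SimConfig) -> SimResult:
    """Simulate the pedigree and merit index of a two-regime breeding scheme.

    Each year, sire candidates are the males whose age at the offspring's
    birth falls near the regime's mean parental age; the top fraction by
    observed index is retained and usage across the first ``n_sires`` of
    them follows geometric weights w_k ~ (1-s)^k over merit rank (s is
    the regime's skew).  Dams are drawn broadly (uniformly over the top
    ``dam_top_frac`` by index).  Breeding values descend as parental mean
    plus a Mendelian-sampling deviate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    ids: list[str] = []
    sire_of: list[str | None] = []
    dam_of: list[str | None] = []
    bdates: list = []
    sexes: list[str] = []
    bv: list[float] = []
    by_year_sex: dict[tuple[int, str], list[int]] = {}

    def add(iid, sire, dam, date, sex, value):
        k = len(ids)
        ids.append(iid)
        sire_of.append(sire)
        dam_of.append(dam)
        bdates.append(date)
        sexes.append(sex)
        bv.append(value)
        by_year_sex.setdefault((date.year, sex), []).append(k)
        return k

    # founders spread over the years before the study window
    founder_years = np.arange(
        cfg.start_year - 1 - cfg.founder_year_span, cfg.start_year
    )
    for sex, count in (("M", cfg.n_founder_males), ("F", cfg.n_founder_females)):
        years = rng.choice(founder_years, size=count)
        days = rng.integers(0, 365, size=count)
        # founders carry the pre-existing genetic trend of the population
        values = rng.normal(
            cfg.founder_trend_per_year * (years - cfg.start_year).astype(float),
            cfg.genetic_sd,
        )
        for j in range(count):
            date = pd.Timestamp(int(years[j]), 1, 1) + pd.Timedelta(int(days[j]), "D")
            add(f"F{sex}{j:04d}", None, None, date, sex, values[j])

    sigma_ms = cfg.genetic_sd / np.sqrt(2.0)
    noise = {
        k: float(rng.normal(0.0, cfg.noise_sd)) for k in range(len(ids))
    }
    gebv_noise: dict[int, float] = {}

    def observed(k: int) -> float:
        return bv[k] + noise[k]

    def gebv(k: int) -> float:
        # genomic proxy: tighter around the true breeding value than the index
        if k not in gebv_noise:
            gebv_noise[k] = float(rng.normal(0.0, cfg.gebv_noise_sd))
        return bv[k] + gebv_noise[k]

    def cohort_year(year: int, age_months: float) -> int:
        """Parent birth year for one drawn parental age, clipped to cohorts
        that actually contain individuals of the needed sex later."""
        a = rng.normal(age_months, cfg.parental_age_sd)
        a = max(a, 13.0)  # parents are at least just over a year old
        return year - int(round(a / 12.0))

    def pick_parent(year: int, sex: str, age_months: float,
                    top_frac: float, n_top: int, skew: float,
                    criterion) -> int:
        y = cohort_year(year, age_months)
        pool: list[int] = []
        widen = 0
        while not pool:
            for yy in range(y - widen, y + widen + 1):
                if yy < year:
                    pool = pool + by_year_sex.get((yy, sex), [])
            widen += 1
            if widen > 20:
                raise ValueError(f"no {sex} parent candidates for year {year}")
        ranked = sorted(pool, key=criterion, reverse=True)
        n_keep = max(1, min(n_top, int(round(top_frac * len(ranked)))))
        elite = ranked[:n_keep]
        w = (1.0 - skew) ** np.arange(len(elite))
        w /= w.sum()
        return elite[rng.choice(len(elite), p=w)]

    for year in range(cfg.start_year, cfg.end_year + 1):
        pre = cfg.regime(year) == "PTS"
        n_off = cfg.cohort_size_pre if pre else cfg.cohort_size_post
        age = cfg.mean_parental_age_pre if pre else cfg.mean_parental_age_post
        skew = cfg.sire_skew_pre if pre else cfg.sire_skew_post
        n_sires = cfg.n_sires_pre if pre else cfg.n_sires_post
        top_frac = cfg.sel_top_frac_pre if pre else cfg.sel_top_frac_post

        days = rng.integers(0, 365, size=n_off)
        ms = rng.normal(0.0, sigma_ms, size=n_off)
        eps = rng.normal(0.0, cfg.noise_sd, size=n_off)
        sex_draw = rng.random(n_off) < 0.5
        crit = observed if pre else gebv
        for j in range(n_off):
            s = pick_parent(year, "M", age, top_frac, n_sires, skew, crit)
            d = pick_parent(year, "F", age, cfg.dam_top_frac, 10**9, 0.0, crit)
            date = pd.Timestamp(year, 1, 1) + pd.Timedelta(int(days[j]), "D")
            value = 0.5 * (bv[s] + bv[d]) + ms[j]
            k = add(
                f"Y{year}N{j:04d}",
                ids[s],
                ids[d],
                date,
                "M" if sex_draw[j] else "F",
                value,
            )
            noise[k] = float(eps[j])

    groups = [
        cfg.regime(d.year) if d.year >= cfg.start_year else None for d in bdates
    ]
    ped = Pedigree.from_records(
        list(zip(ids, sire_of, dam_of, bdates, groups))
    )
    index = pd.Series(
        {ids[k]: bv[k] + noise[k] for k in range(len(ids))}, name="index"
    )
    bvs = pd.Series({ids[k]: bv[k] for k in range(len(ids))}, name="breeding_value")
    sex = pd.Series({ids[k]: sexes[k] for k in range(len(ids))}, name="sex")

    from .demography import contributions_from_pedigree

    contrib = contributions_from_pedigree(ped)
    contrib = contrib[sex.reindex(contrib["id"]).to_numpy() == "M"].reset_index(
        drop=True
    )
    return SimResult(ped, contrib, index, bvs, sex)


def simulate_pedigree(cfg: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree and sire contribution table of the simulated scheme."""
    res = simulate_scheme(cfg)
    return res.pedigree, res.contributions


def simulate_index(ped: Pedigree, cfg: SimConfig) -> pd.Series:
    """Observed merit index per individual for the scheme of ``cfg``.

    Deterministic in ``cfg.seed`` and consistent with
    :func:`simulate_pedigree` run on the same config.
    """
    res = simulate_scheme(cfg)
    if list(res.pedigree.ids) != list(ped.ids) and set(res.pedigree.ids) != set(
        ped.ids
    ):
        raise ValueError("pedigree does not match the scheme of this config")
    return res.index.reindex(ped.ids)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

Segment = tuple[int, int, int]  # start_bp, end_bp (inclusive), founder label


def _recombine(
    hap_a: list[Segment],
    hap_b: list[Segment],
    length_bp: int,
    length_cM: float,
    rng: np.random.Generator,
) -> list[Segment]:
    """One meiosis under the Haldane model (Poisson crossovers, uniform map)."""
    n_xo = rng.poisson(length_cM / 100.0)
    cuts = np.sort(rng.integers(1, length_bp, size=n_xo)) if n_xo else np.array([], int)
    current = int(rng.integers(0, 2))
    haps = (hap_a, hap_b)
    out: list[Segment] = []
    start = 1
    bounds = list(cuts) + [length_bp + 1]
    for cut in bounds:
        end = int(cut) - 1
        if end >= start:
            for s, e, lab in haps[current]:
                if e < start or s > end:
                    continue
                out.append((max(s, start), min(e, end), lab))
        current ^= 1
        start = int(cut)
    # merge adjacent same-label pieces
    merged: list[Segment] = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] + 1 == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


@dataclass
class GeneDropResult:
    """Gametes with founder-origin labels, plus lazily realized genotypes."""

    pedigree: Pedigree
    cfg: SimConfig
    gametes: list  # per individual: list over chromosomes of (pat, mat) segment lists
    n_labels: int
    _rng_alleles: np.random.Generator = field(repr=False, default=None)
    _founder_alleles: np.ndarray | None = field(repr=False, default=None)
    _positions: list[np.ndarray] | None = field(repr=False, default=None)

    def ibd_tracks(self, iid: str) -> list[pd.DataFrame]:
        """Per-chromosome partition into autozygous / non-autozygous tracts."""
        k = self.pedigree.index_of(iid)
        out = []
        for chrom in range(self.cfg.n_chromosomes):
            pat, mat = self.gametes[k][chrom]
            rows = []
            for s, e, auto in _intersect_labels(pat, mat):
                rows.append((s, e, auto))
            out.append(
                pd.DataFrame(rows, columns=["start_bp", "end_bp", "autozygous"])
            )
        return out

    def f_true(self, iid: str) -> float:
        """Realized IBD fraction: autozygous length / genome length."""
        k = self.pedigree.index_of(iid)
        total = self.cfg.n_chromosomes * self.cfg.chrom_length_bp
        auto = 0
        for chrom in range(self.cfg.n_chromosomes):
            pat, mat = self.gametes[k][chrom]
            for s, e, is_auto in _intersect_labels(pat, mat):
                if is_auto:
                    auto += e - s + 1
        return auto / total

    def f_true_all(self) -> pd.Series:
        return pd.Series(
            {iid: self.f_true(iid) for iid in self.pedigree.ids}, name="F_true"
        )

    # -- genotypes ---------------------------------------------------------

    def _ensure_map(self) -> None:
        if self._positions is not None:
            return
        rng = self._rng_alleles
        spacing = self.cfg.chrom_length_bp / self.cfg.snps_per_chromosome
        self._positions = []
        for _ in range(self.cfg.n_chromosomes):
            jitter = rng.uniform(-0.3, 0.3, size=self.cfg.snps_per_chromosome)
            pos = ((np.arange(self.cfg.snps_per_chromosome) + 0.5 + jitter) * spacing)
            pos = np.unique(np.clip(pos.astype(np.int64), 1, self.cfg.chrom_length_bp))
            self._positions.append(pos)
        n_snps = sum(len(p) for p in self._positions)
        freqs = rng.uniform(
            self.cfg.founder_maf_low, self.cfg.founder_maf_high, size=n_snps
        )
        if self.cfg.founder_ld_blocks:
            self._founder_alleles = self._block_founder_alleles(freqs, rng)
        else:
            self._founder_alleles = (
                rng.random((self.n_labels, n_snps)) < freqs
            ).astype(np.int8)

    def _block_founder_alleles(self, freqs, rng) -> np.ndarray:
        """Copy founder haplotypes from a small pool in blocks (background LD)."""
        n_snps = freqs.size
        pool = (rng.random((self.cfg.n_founder_hap_pool, n_snps)) < freqs).astype(
            np.int8
        )
        out = np.empty((self.n_labels, n_snps), dtype=np.int8)
        block = max(
            1,
            int(
                self.cfg.ld_block_cM
                / self.cfg.chrom_length_cM
                * self.cfg.snps_per_chromosome
            ),
        )
        n_blocks = (n_snps + block - 1) // block
        for lab in range(self.n_labels):
            picks = rng.integers(0, self.cfg.n_founder_hap_pool, size=n_blocks)
            for b in range(n_blocks):
                sl = slice(b * block, min((b + 1) * block, n_snps))
                out[lab, sl] = pool[picks[b], sl]
        return out

    def panel(self) -> GenotypePanel:
        """Realize allele states on the SNP map (genotype = allele-count sum)."""
        self._ensure_map()
        ped = self.pedigree
        n = len(ped)
        offsets = np.cumsum([0] + [len(p) for p in self._positions])
        geno = np.zeros((n, offsets[-1]), dtype=np.int8)
        for k in range(n):
            for chrom in range(self.cfg.n_chromosomes):
                pos = self._positions[chrom]
                off = offsets[chrom]
                for hap in self.gametes[k][chrom]:
                    for s, e, lab in hap:
                        i0 = int(np.searchsorted(pos, s, side="left"))
                        i1 = int(np.searchsorted(pos, e, side="right"))
                        geno[k, off + i0 : off + i1] += self._founder_alleles[
                            lab, off + i0 : off + i1
                        ]
        snp_map = pd.concat(
            [
                pd.DataFrame(
                    {
                        "chrom": str(chrom + 1),
                        "snp_id": [
                            f"snp{chrom + 1}_{j}" for j in range(len(pos))
                        ],
                        "bp": pos,
                        "cM": pos * (self.cfg.chrom_length_cM / self.cfg.chrom_length_bp),
                    }
                )
                for chrom, pos in enumerate(self._positions)
            ],
            ignore_index=True,
        )
        return GenotypePanel(list(ped.ids), geno, snp_map)


def _intersect_labels(
    pat: list[Segment], mat: list[Segment]
) -> list[tuple[int, int, bool]]:
    """Overlay two labelled gametes; True where founder labels coincide."""
    out = []
    i = j = 0
    while i < len(pat) and j < len(mat):
        s = max(pat[i][0], mat[j][0])
        e = min(pat[i][1], mat[j][1])
        if s <= e:
            out.append((s, e, pat[i][2] == mat[j][2]))
        if pat[i][1] < mat[j][1]:
            i += 1
        else:
            j += 1
    return out


def gene_drop(ped: Pedigree, cfg: SimConfig, seed: int | None = None) -> GeneDropResult:
    """Drop labelled founder haplotypes through the pedigree.

    Founders (and unknown-parent slots) receive fresh labelled haplotypes;
    every transmission is one recombinant meiosis per chromosome.  Allele
    states are realized lazily from per-SNP founder frequencies when the
    genotype panel is requested, so IBD-only studies skip that cost.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 23])
    )
    rng_alleles = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 29])
    )
    n = len(ped)
    L_bp, L_cM = cfg.chrom_length_bp, cfg.chrom_length_cM
    gametes: list = [None] * n
    label = 0

    def fresh_hap() -> list[list[Segment]]:
        nonlocal label
        lab = label
        label += 1
        return [[(1, L_bp, lab)] for _ in range(cfg.n_chromosomes)]

    for k in range(n):
        s, d = ped.sire[k], ped.dam[k]
        sides = []
        for p in (s, d):
            if p == UNKNOWN:
                sides.append(fresh_hap())
            else:
                pat, mat = zip(*gametes[p])
                sides.append(
                    [
                        _recombine(pat[c], mat[c], L_bp, L_cM, rng)
                        for c in range(cfg.n_chromosomes)
                    ]
                )
        gametes[k] = list(zip(sides[0], sides[1]))
    return GeneDropResult(ped, cfg, gametes, label, rng_alleles)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export(
    panel: GenotypePanel,
    ped: Pedigree,
    index: pd.Series,
    outdir,
    f_true: pd.Series | None = None,
    prefix: str = "sim",
) -> dict:
    """Write PLINK bed/bim/fam, pedigree CSV, index CSV and a truth TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plink": outdir / prefix,
        "pedigree": outdir / f"{prefix}_pedigree.csv",
        "index": outdir / f"{prefix}_index.csv",
        "truth": outdir / f"{prefix}_truth.tsv",
    }
    write_plink(panel, paths["plink"])
    ped_df = ped.to_frame()
    ped_df["sire"] = ped_df["sire"].fillna("0")
    ped_df["dam"] = ped_df["dam"].fillna("0")
    ped_df["birth_date"] = pd.Series(ped.birth_date).dt.strftime("%Y-%m-%d").fillna("")
    ped_df.to_csv(paths["pedigree"], index=False)
    idx = index.reindex(ped.ids)
    years = pd.Series(ped.birth_date, index=ped.ids).dt.year
    pd.DataFrame(
        {"id": ped.ids, "birth_year": years.to_numpy(), "index": idx.to_numpy()}
    ).to_csv(paths["index"], index=False)
    if f_true is not None:
        f_true.rename("F_true").rename_axis("id").to_frame().to_csv(
            paths["truth"], sep="\t"
        )
    return paths
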