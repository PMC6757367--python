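"""Pedigree container and pedigree-based measures of genetic diversity.

A pedigree is a directed acyclic graph of parent links with optional birth
dates and cohort labels.  From it we derive the classical quantities used to
monitor diversity in livestock populations:

* ``F_ped`` — the inbreeding coefficient, the probability that the two
  alleles an individual carries at a locus are identical by descent (IBD);
* ``f_ped`` — the kinship (coancestry) coefficient between two individuals,
  the probability that one allele drawn from each is IBD;
* truncated-generation inbreeding (``F_ped`` restricted to the most recent
  *k* generations of ancestry, five in the usual convention);
* pedigree depth (longest ancestral path) and the parental generation
  interval ``I1`` in months.

Unknown parents are treated as non-inbred, unrelated founders throughout,
which is the standard assumption behind pedigree-based estimates and the
reason they form a lower bound on realized autozygosity.

Inbreeding is computed with the tabular recursion of Meuwissen & Luo, which
scales to pedigrees of ~1e5 individuals over ~15 generations without ever
forming the full relationship matrix.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = -1

#: mean calendar month in days; used to express generation intervals in months
DAYS_PER_MONTH = 30.4375


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids...)."""


@dataclass
class Pedigree:
    """A validated pedigree in topological order (parents before offspring).

    Attributes
    ----------
    ids : list of str
        Individual identifiers, in topological order.
    sire, dam : np.ndarray of int
        Index of each individual's sire/dam in ``ids``; ``UNKNOWN`` (-1) for
        founders or missing parents.
    birth_date : np.ndarray of datetime64[D]
        Birth dates; ``NaT`` when unknown.
    group : list of str or None
        Optional cohort label per individual.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    birth_date: np.ndarray
    group: list[str | None]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {iid: k for k, iid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, iid: str) -> int:
        try:
            return self._index[iid]
        except KeyError:
            raise KeyError(f"unknown individual id: {iid!r}") from None

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        k = self.index_of(iid)
        s, d = self.sire[k], self.dam[k]
        return (
            self.ids[s] if s != UNKNOWN else None,
            self.ids[d] if d != UNKNOWN else None,
        )

    def is_founder(self, iid: str) -> bool:
        k = self.index_of(iid)
        return self.sire[k] == UNKNOWN and self.dam[k] == UNKNOWN

    @classmethod
    def from_records(
        cls,
        records: list[tuple],
    ) -> "Pedigree":
        """Build from (id, sire, dam[, birth_date[, group]]) tuples.

        Parent entries that never appear as a record id are auto-registered
        as founders.  ``None``, ``""`` and ``"0"`` denote unknown parents.
        """
        rows = []
        for rec in records:
            iid, sire, dam = rec[0], rec[1], rec[2]
            bdate = rec[3] if len(rec) > 3 else None
            grp = rec[4] if len(rec) > 4 else None
            rows.append((str(iid), _norm(sire), _norm(dam), bdate, grp))

        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise PedigreeError(f"duplicate individual id: {dup!r}")
        known = set(ids)

        # auto-register implicit founders
        implicit: list[str] = []
        for _, s, d, _, _ in rows:
            for p in (s, d):
                if p is not None and p not in known:
                    known.add(p)
                    implicit.append(p)
        if implicit:
            logger.warning(
                "%d parent id(s) never appear as records; added as founders "
                "(first: %r)", len(implicit), implicit[0]
            )
        all_rows = [(p, None, None, None, None) for p in implicit] + rows

        order = _toposort(all_rows)
        idx = {all_rows[k][0]: pos for pos, k in enumerate(order)}
        n = len(all_rows)
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        bdates = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
        groups: list[str | None] = [None] * n
        ids_sorted = [""] * n
        for k in order:
            iid, s, d, bd, grp = all_rows[k]
            pos = idx[iid]
            ids_sorted[pos] = iid
            if s is not None:
                sire[pos] = idx[s]
            if d is not None:
                dam[pos] = idx[d]
            if bd is not None and not pd.isna(bd):
                bdates[pos] = np.datetime64(pd.Timestamp(bd).date(), "D")
            groups[pos] = grp
        return cls(ids_sorted, sire, dam, bdates, groups)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (id, sire, dam, birth_date, group), topological order."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.ids[s] if s != UNKNOWN else None for s in self.sire],
                "dam": [self.ids[d] if d != UNKNOWN else None for d in self.dam],
                "birth_date": self.birth_date,
                "group": self.group,
            }
        )


def _norm(parent) -> str | None:
    if parent is None:
        return None
    p = str(parent).strip()
    if p in ("", "0", "nan", "NaN"):
        return None
    return p


def _toposort(rows: list[tuple]) -> list[int]:
    """Kahn topological sort; raises PedigreeError naming a cycle member."""
    idx = {r[0]: k for k, r in enumerate(rows)}
    n = len(rows)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for k, (_, s, d, _, _) in enumerate(rows):
        for p in (s, d):
            if p is not None:
                children[idx[p]].append(k)
                indeg[k] += 1
    queue = [k for k in range(n) if indeg[k] == 0]
    order: list[int] = []
    while queue:
        k = queue.pop()
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < n:
        culprit = next(rows[k][0] for k in range(n) if indeg[k] > 0)
        raise PedigreeError(
            f"pedigree contains a cycle involving individual {culprit!r}"
        )
    return order


def load_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam, birth_date[, group].

    Unknown parents are encoded as empty cells or ``"0"``.  Parents that
    never appear as records are auto-registered as founders (logged).
    Duplicate ids and ancestry cycles are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "birth_date"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree CSV lacks required columns: {sorted(missing)}")
    has_group = "group" in df.columns
    records = []
    for row in df.itertuples(index=False):
        bd = row.birth_date if row.birth_date else None
        records.append(
            (row.id, row.sire, row.dam, bd, row.group if has_group else None)
        )
    return Pedigree.from_records(records)


# ---------------------------------------------------------------------------
# inbreeding: Meuwissen–Luo tabular recursion
# ---------------------------------------------------------------------------

def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficient F_ped for every individual.

    Uses the tabular method: with animals ordered so parents precede
    offspring, the self-relationship a_ii = 1 + F_i is accumulated by
    tracing individual i's ancestor contributions L and the within-family
    segregation variances D, where D_k = 0.5 - 0.25 (F_sire(k) + F_dam(k))
    (1 for founders, 0.75 - 0.25 F_p with a single known parent).
    Equivalent to Wright's path-counting sum but polynomial time.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.empty(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            D[i] = 1.0
            F[i] = 0.0
            continue
        if s == UNKNOWN:
            D[i] = 0.75 - 0.25 * F[d]
        elif d == UNKNOWN:
            D[i] = 0.75 - 0.25 * F[s]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        # trace a_ii = sum_k L_k^2 D_k over i and its ancestors, youngest first
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        in_heap = {i}
        a_ii = 0.0
        while heap:
            k = -heapq.heappop(heap)
            lk = L.pop(k)
            a_ii += lk * lk * D[k]
            for p in (sire[k], dam[k]):
                if p != UNKNOWN:
                    if p in L:
                        L[p] += 0.5 * lk
                    else:
                        L[p] = 0.5 * lk
                        if p not in in_heap:
                            heapq.heappush(heap, -p)
                            in_heap.add(p)
            in_heap.discard(k)
        F[i] = a_ii - 1.0
    return pd.Series(F, index=ped.ids, name="F_ped")


def kinship(ped: Pedigree, ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise kinship table f_ped over ``ids`` (default: all individuals).

    Built from the additive-relationship recursion a(i,j) =
    0.5 (a(sire_i, j) + a(dam_i, j)) for i later than j in topological
    order, a(i,i) = 1 + F_i, restricted to the ancestors of the requested
    set; kinship is f = a / 2, so f(i,i) = 0.5 (1 + F_i).
    """
    if ids is None:
        ids = list(ped.ids)
    bad = [i for i in ids if i not in ped._index]
    if bad:
        raise KeyError(f"ids not in pedigree: {bad}")
    # restrict to ancestors of the requested set
    needed = np.zeros(len(ped), dtype=bool)
    stack = [ped.index_of(i) for i in ids]
    while stack:
        k = stack.pop()
        if needed[k]:
            continue
        needed[k] = True
        for p in (ped.sire[k], ped.dam[k]):
            if p != UNKNOWN:
                stack.append(p)
    sub = np.flatnonzero(needed)  # ascending = topological
    pos = {k: j for j, k in enumerate(sub)}
    m = len(sub)
    A = np.zeros((m, m))
    for j, k in enumerate(sub):
        s, d = ped.sire[k], ped.dam[k]
        js = pos.get(s, None)
        jd = pos.get(d, None)
        row = np.zeros(j)
        if js is not None:
            row += 0.5 * A[js, :j]
        if jd is not None:
            row += 0.5 * A[jd, :j]
        A[j, :j] = row
        A[:j, j] = row
        f_self = 0.0 if js is None or jd is None else 0.5 * A[js, jd]
        A[j, j] = 1.0 + f_self
    take = [pos[ped.index_of(i)] for i in ids]
    K = 0.5 * A[np.ix_(take, take)]
    return pd.DataFrame(K, index=ids, columns=ids)


def mean_kinship(ped: Pedigree, ids: list[str], include_self: bool = False) -> float:
    """Mean pairwise kinship over distinct pairs in ``ids``.

    ``include_self=True`` averages over the full matrix including the
    diagonal self-kinship terms instead.
    """
    K = kinship(ped, ids).to_numpy()
    n = K.shape[0]
    if include_self:
        return float(K.mean())
    if n < 2:
        raise ValueError("need at least two individuals for pairwise kinship")
    off = K[np.triu_indices(n, k=1)]
    return float(off.mean())


# ---------------------------------------------------------------------------
# truncation to the last k generations
# ---------------------------------------------------------------------------

def truncate(ped: Pedigree, targets: list[str], depth: int = 5) -> Pedigree:
    """Pedigree restricted to the last ``depth`` generations above ``targets``.

    Ancestors whose minimum path distance from the nearest target equals
    ``depth`` have their parent links severed (become founders); deeper
    ancestors are dropped.  Truncating at depth d then d' < d equals
    truncating at d' directly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    dist = {}
    frontier = []
    for t in targets:
        k = ped.index_of(t)
        dist[k] = 0
        frontier.append(k)
    while frontier:
        nxt = []
        for k in frontier:
            if dist[k] >= depth:
                continue
            for p in (ped.sire[k], ped.dam[k]):
                if p != UNKNOWN and dist.get(p, depth + 1) > dist[k] + 1:
                    dist[p] = dist[k] + 1
                    nxt.append(p)
        frontier = nxt
    keep = sorted(dist)
    records = []
    for k in keep:
        sever = dist[k] >= depth
        s, d = ped.sire[k], ped.dam[k]
        records.append(
            (
                ped.ids[k],
                ped.ids[s] if not sever and s != UNKNOWN else None,
                ped.ids[d] if not sever and d != UNKNOWN else None,
                ped.birth_date[k] if not pd.isna(ped.birth_date[k]) else None,
                ped.group[k],
            )
        )
    return Pedigree.from_records(records)


def truncated_inbreeding(
    ped: Pedigree, targets: list[str] | None = None, depth: int = 5
) -> pd.Series:
    """F_ped over the last ``depth`` generations only (F_ped_5gen by default).

    Computed per target on its own truncated sub-pedigree, so one
    individual's deep ancestry cannot re-enter another's window through a
    shared ancestor.
    """
    if targets is None:
        targets = list(ped.ids)
    out = {}
    for t in targets:
        sub = truncate(ped, [t], depth)
        out[t] = inbreeding(sub)[t]
    return pd.Series(out, name=f"F_ped_{depth}gen").reindex(targets)


# ---------------------------------------------------------------------------
# depth and generation interval
# ---------------------------------------------------------------------------

def depth_longest(ped: Pedigree, iid: str | None = None):
    """Longest ancestral path to any founder (founder -> 0).

    Returns a Series for all ids, or an int when ``iid`` is given.
    """
    n = len(ped)
    depth = np.zeros(n, dtype=np.int64)
    for k in range(n):
        for p in (ped.sire[k], ped.dam[k]):
            if p != UNKNOWN:
                depth[k] = max(depth[k], depth[p] + 1)
    series = pd.Series(depth, index=ped.ids, name="depth_longest")
    return int(series[iid]) if iid is not None else series


def depth_mean_path(ped: Pedigree, iid: str | None = None):
    """Mean ancestral path length: 1 + average over known parents, recursively.

    An alternative summary of pedigree completeness; the longest path is the
    primary definition.
    """
    n = len(ped)
    depth = np.zeros(n)
    for k in range(n):
        ps = [p for p in (ped.sire[k], ped.dam[k]) if p != UNKNOWN]
        if ps:
            depth[k] = 1.0 + float(np.mean([depth[p] for p in ps]))
    series = pd.Series(depth, index=ped.ids, name="depth_mean_path")
    return float(series[iid]) if iid is not None else series


def generation_interval(ped: Pedigree, iid: str | None = None):
    """Parental generation interval I1 in months (30.4375-day months).

    Mean, over parents with known birth dates, of the individual's birth
    date minus the parent's.  NaN when no dated parent exists.
    """
    n = len(ped)
    out = np.full(n, np.nan)
    bd = ped.birth_date
    for k in range(n):
        if pd.isna(bd[k]):
            continue
        diffs = []
        for p in (ped.sire[k], ped.dam[k]):
            if p != UNKNOWN and not pd.isna(bd[p]):
                days = (bd[k] - bd[p]).astype("timedelta64[D]").astype(float)
                diffs.append(days / DAYS_PER_MONTH)
        if diffs:
            out[k] = float(np.mean(diffs))
    series = pd.Series(out, index=ped.ids, name="I1_months")
    return float(series[iid]) if iid is not None else series


def pedigree_statistics(ped: Pedigree, depth: int = 5) -> pd.DataFrame:
    """Per-individual summary: F_ped, truncated F, depth and I1 (months)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        df = pd.DataFrame(
            {
                "F_ped": inbreeding(ped),
                f"F_ped_{depth}gen": truncated_inbreeding(ped, depth=depth),
                "depth_longest": depth_longest(ped),
                "I1_months": generation_interval(ped),
            }
        )
    df.index.name = "id"
    return df
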