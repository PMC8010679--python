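"""LTR retroelement insertion-time dating and cross-genome recency contrast.

The two long terminal repeats of a retroelement are identical at the moment
of insertion and then diverge neutrally, so their substitution distance
clocks the insertion. Per element the pipeline is

    align 5'/3' LTRs  ->  (p, q) transition/transversion frequencies
                      ->  Kimura two-parameter distance
                          K = -1/2 ln[(1 - 2p - q) sqrt(1 - 2q)]
                      ->  insertion time T = K / (2 r)

with r the per-year substitution rate (default 1.3e-8 subs/site/year) and a
recency cutoff (default 0.5 My) splitting elements into "recent" and "old".
Two genomes' recent/old counts are contrasted with an exact two-sided
Fisher test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

REQUIRED_DOMAINS = frozenset({"GAG", "RT", "RH", "AP", "INT"})

DEFAULT_RATE = 1.3e-8  # substitutions / site / year
DEFAULT_RECENT_THRESHOLD = 5e5  # years

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class LTRElement:
    """One annotated LTR retroelement with its two LTR sequences."""

    element_id: str
    family: str
    ltr5: str
    ltr3: str
    superfamily: str = ""
    domains_present: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.ltr5 or not self.ltr3:
            raise ValueError(f"{self.element_id}: both LTR sequences must be non-empty")
        if not self.family:
            object.__setattr__(self, "family", "unclassified")
        object.__setattr__(self, "domains_present", frozenset(self.domains_present))

    @property
    def full_length(self) -> bool:
        return REQUIRED_DOMAINS <= self.domains_present


@dataclass(frozen=True)
class K2PEstimate:
    """Transition/transversion frequencies and K2P distance for one LTR pair."""

    p: float
    q: float
    n_sites: int
    K: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0 or self.p + self.q > 1 + 1e-12:
            raise ValueError(f"invalid frequencies p={self.p}, q={self.q}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass(frozen=True)
class InsertionTimeEstimate:
    """Element age in years with the rate and recency threshold used."""

    element_id: str
    T: float
    r_used: float
    recent: bool
    threshold_years: float


def filter_full_length(elements: list[LTRElement]) -> list[LTRElement]:
    """Keep elements with similarity to all of GAG, RT, RH, AP and INT.

    Elements missing any of the five retroelement protein domains are
    treated as truncated/degenerate and excluded from dating.
    """
    return [e for e in elements if e.full_length]


# ---------------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment parameters (affine gaps; end gaps penalised)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= self.match:
            raise ValueError("need mismatch < match and match > 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


COL_MATCH = "match"
COL_TRANSITION = "transition"
COL_TRANSVERSION = "transversion"
COL_GAP = "gap"
COL_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LTRAlignment:
    """End-to-end pairwise alignment of a 5' vs 3' LTR with typed columns."""

    aligned5: str
    aligned3: str
    score: float
    columns: tuple[str, ...]

    def count(self, kind: str) -> int:
        return self.columns.count(kind)


def classify_column(a: str, b: str) -> str:
    if a == "-" or b == "-":
        return COL_GAP
    if a == "N" or b == "N":
        return COL_AMBIGUOUS
    if a == b:
        return COL_MATCH
    if ({a, b} <= _PURINES) or ({a, b} <= _PYRIMIDINES):
        return COL_TRANSITION
    return COL_TRANSVERSION


def _build_aligner(scoring: AlignmentScoring):
    from Bio import Align
    from Bio.Align import substitution_matrices

    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if x == "N" or y == "N":
                mat[x, y] = 0.0  # ambiguous: neither reward nor penalise
            elif x == y:
                mat[x, y] = scoring.match
            else:
                mat[x, y] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


_ALIGNER_CACHE: dict[AlignmentScoring, object] = {}


def align_ltr_pair(element: LTRElement,
                   scoring: AlignmentScoring | None = None) -> LTRAlignment:
    """Globally align an element's 5' and 3' LTRs and type every column.

    The alignment is end-to-end (Needleman–Wunsch with affine gap costs);
    each column is classified as match, transition, transversion, gap or
    ambiguous (N). Among co-optimal alignments the aligner's first
    deterministic traceback is used.
    """
    scoring = scoring or AlignmentScoring()
    for name, seq in (("ltr5", element.ltr5), ("ltr3", element.ltr3)):
        if not seq:
            raise ValueError(f"{element.element_id}: empty {name}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{element.element_id}: {name} contains non-ACGTN characters {sorted(bad)}")
    aligner = _ALIGNER_CACHE.get(scoring)
    if aligner is None:
        aligner = _ALIGNER_CACHE[scoring] = _build_aligner(scoring)
    aln = aligner.align(element.ltr5, element.ltr3)[0]
    a, b = str(aln[0]), str(aln[1])
    cols = tuple(classify_column(x, y) for x, y in zip(a, b))
    return LTRAlignment(aligned5=a, aligned3=b, score=float(aln.score),
                        columns=cols)


def substitution_frequencies(alignment: LTRAlignment) -> tuple[float, float, int]:
    """Transition frequency p, transversion frequency q and compared sites.

    Gap and ambiguous columns are pairwise-deleted: only columns with an
    unambiguous nucleotide in both rows count towards ``n_sites``.
    """
    n_ts = alignment.count(COL_TRANSITION)
    n_tv = alignment.count(COL_TRANSVERSION)
    n_sites = alignment.count(COL_MATCH) + n_ts + n_tv
    if n_sites == 0:
        raise ValueError("no comparable (non-gap, non-N) columns; estimate undefined")
    return n_ts / n_sites, n_tv / n_sites, n_sites


def k2p_distance(p: float, q: float, n_sites: int = 1) -> K2PEstimate:
    """Kimura two-parameter distance K = -1/2 ln[(1-2p-q) sqrt(1-2q)].

    Saturated inputs (either log argument factor <= 0) yield a flagged
    estimate with ``K = nan``; such pairs are undatable and excluded from
    age summaries.
    """
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        logger.warning("saturated LTR pair (p=%.4f, q=%.4f): excluded from dating", p, q)
        return K2PEstimate(p=p, q=q, n_sites=n_sites, K=float("nan"), saturated=True)
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PEstimate(p=p, q=q, n_sites=n_sites, K=K, saturated=False)


def insertion_time(K: float, r: float = DEFAULT_RATE,
                   threshold_years: float = DEFAULT_RECENT_THRESHOLD,
                   element_id: str = "") -> InsertionTimeEstimate:
    """Insertion age T = K / (2 r); recent iff strictly T < threshold."""
    if r <= 0:
        raise ValueError(f"rate r must be > 0, got {r}")
    if K < 0:
        raise ValueError(f"distance K must be >= 0, got {K}")
    T = K / (2.0 * r)
    # boundary ages count as old; the isclose guard keeps exact-threshold
    # cases (e.g. K = 0.013 at the default rate) from flipping on float noise
    recent = T < threshold_years and not math.isclose(
        T, threshold_years, rel_tol=1e-12)
    return InsertionTimeEstimate(element_id=element_id, T=T, r_used=r,
                                 recent=recent,
                                 threshold_years=threshold_years)


def date_elements(elements: list[LTRElement],
                  scoring: AlignmentScoring | None = None,
                  r: float = DEFAULT_RATE,
                  threshold_years: float = DEFAULT_RECENT_THRESHOLD,
                  require_full_length: bool = True) -> pd.DataFrame:
    """Run the full per-element dating pipeline.

    Returns one row per retained element with columns element_id, family,
    p, q, n_sites, K, T_years, recent, saturated. Saturated pairs keep a
    row (NaN age) so the undatable tally is visible.
    """
    retained = filter_full_length(elements) if require_full_length else list(elements)
    rows = []
    for el in retained:
        aln = align_ltr_pair(el, scoring)
        p, q, n_sites = substitution_frequencies(aln)
        est = k2p_distance(p, q, n_sites)
        if est.saturated:
            rows.append({"element_id": el.element_id, "family": el.family,
                         "p": p, "q": q, "n_sites": n_sites, "K": float("nan"),
                         "T_years": float("nan"), "recent": False,
                         "saturated": True})
            continue
        t = insertion_time(est.K, r=r, threshold_years=threshold_years,
                           element_id=el.element_id)
        rows.append({"element_id": el.element_id, "family": el.family,
                     "p": p, "q": q, "n_sites": n_sites, "K": est.K,
                     "T_years": t.T, "recent": t.recent, "saturated": False})
    return pd.DataFrame(rows, columns=["element_id", "family", "p", "q",
                                       "n_sites", "K", "T_years", "recent",
                                       "saturated"])


# ---------------------------------------------------------------------------
# Cross-genome recency contrast


@dataclass(frozen=True)
class RecencyTable:
    """2x2 counts: rows = genome A/B, columns = recent/old."""

    recent_a: int
    old_a: int
    recent_b: int
    old_b: int

    def __post_init__(self) -> None:
        for v in (self.recent_a, self.old_a, self.recent_b, self.old_b):
            if v < 0:
                raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.recent_a, self.old_a],
                         [self.recent_b, self.old_b]], dtype=np.int64)


def recency_contingency(times_a: list[InsertionTimeEstimate],
                        times_b: list[InsertionTimeEstimate]) -> RecencyTable:
    """Tabulate recent/old counts per genome for a two-genome contrast."""
    if not times_a or not times_b:
        raise ValueError("both genomes must contribute at least one dated element")
    ra = sum(t.recent for t in times_a)
    rb = sum(t.recent for t in times_b)
    return RecencyTable(recent_a=ra, old_a=len(times_a) - ra,
                        recent_b=rb, old_b=len(times_b) - rb)


def fisher_exact(table: RecencyTable | np.ndarray, rel_tol: float = 1e-7) -> float:
    """Two-sided exact Fisher p for a 2x2 table, minimum-likelihood method.

    Enumerates the full hypergeometric support with both margins fixed and
    sums the probabilities of every table whose point probability does not
    exceed that of the observed table (within relative tolerance
    ``rel_tol``) — the convention of R's ``fisher.test``.
    """
    arr = table.as_array() if isinstance(table, RecencyTable) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table cells must be non-negative")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Summaries


def family_copy_summary(elements_a, elements_b) -> pd.DataFrame:
    """Per-family copy counts in two genomes, fold ratios and fractions.

    Accepts lists of :class:`LTRElement` or mappings ``family -> count``.
    ``fold_ratio`` is count_A / count_B, NaN where genome B lacks the
    family; per-genome fractions are of that genome's total element count.
    Families absent from both genomes are omitted.
    """
    def to_counts(x) -> dict[str, int]:
        if isinstance(x, dict):
            return {k: int(v) for k, v in x.items()}
        out: dict[str, int] = {}
        for el in x:
            out[el.family] = out.get(el.family, 0) + 1
        return out

    ca, cb = to_counts(elements_a), to_counts(elements_b)
    families = sorted(set(ca) | set(cb))
    tot_a, tot_b = sum(ca.values()), sum(cb.values())
    rows = []
    for fam in families:
        na, nb = ca.get(fam, 0), cb.get(fam, 0)
        if na == 0 and nb == 0:
            continue
        rows.append({
            "family": fam,
            "count_a": na,
            "count_b": nb,
            "fold_ratio": na / nb if nb else float("nan"),
            "fraction_a": na / tot_a if tot_a else float("nan"),
            "fraction_b": nb / tot_b if tot_b else float("nan"),
        })
    return pd.DataFrame(rows, columns=["family", "count_a", "count_b",
                                       "fold_ratio", "fraction_a", "fraction_b"])


def cumulative_age_curve(times, grid) -> np.ndarray:
    """Fraction of elements with age <= g for each grid point g (ascending).

    ``times`` may be ages in years or :class:`InsertionTimeEstimate` items;
    NaN ages (saturated pairs) are excluded before the curve is formed.
    """
    ages = np.asarray([t.T if isinstance(t, InsertionTimeEstimate) else float(t)
                       for t in times], dtype=float)
    ages = ages[~np.isnan(ages)]
    if ages.size == 0:
        raise ValueError("no datable ages to summarise")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or (np.diff(grid) < 0).any():
        raise ValueError("grid must be non-empty and ascending")
    return np.searchsorted(np.sort(ages), grid, side="right") / ages.size


@dataclass(frozen=True)
class RepeatClusterTable:
    """Read-clustering summary: per-cluster annotation, reads, organelle flag."""

    clusters: pd.DataFrame  # columns: cluster, annotation, reads, organelle
    total_reads: int

    def __post_init__(self) -> None:
        required = {"cluster", "annotation", "reads", "organelle"}
        missing = required - set(self.clusters.columns)
        if missing:
            raise ValueError(f"cluster table missing columns {sorted(missing)}")
        if (self.clusters["reads"] < 0).any():
            raise ValueError("cluster read counts must be non-negative")
        if self.clusters["reads"].sum() > self.total_reads:
            raise ValueError("cluster reads exceed total read count")


def repeat_fraction_renormalize(table: RepeatClusterTable) -> pd.Series:
    """Genome fractions per repeat annotation after organelle-cluster removal.

    Organelle-flagged clusters are dropped and every remaining cluster's
    genome fraction is recomputed against the reduced read total, then
    aggregated by annotation label.
    """
    organelle_reads = int(table.clusters.loc[table.clusters["organelle"], "reads"].sum())
    denom = table.total_reads - organelle_reads
    if denom <= 0:
        raise ValueError("all reads are organelle-derived; nothing to renormalise")
    kept = table.clusters.loc[~table.clusters["organelle"]]
    fractions = kept.groupby("annotation")["reads"].sum() / denom
    return fractions.sort_index()
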