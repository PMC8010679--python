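"""Evidence-based scoring and greedy non-overlapping selection of gene models.

Candidate models from several predictors are pooled, scored against three
evidence sources — RNA-seq support of introns/exons (small positive bonus
per supported feature), protein homology (bonus proportional to hit
significance, weighted by database tier: Arabidopsis > SwissProt > NCBI nr)
and repeat/TE overlap (large negative penalties) — then the final
annotation is assembled greedily: best score first, a candidate is accepted
only if it overlaps no already-accepted model on the same contig and strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

TIER_ORDER = ("arabidopsis", "swissprot", "nr")


@dataclass(frozen=True)
class HomologyHit:
    """One blastp hit: database tier and a non-negative significance score."""

    tier: str
    significance: float

    def __post_init__(self) -> None:
        if self.tier not in TIER_ORDER:
            raise ValueError(f"unknown tier {self.tier!r}; expected one of {TIER_ORDER}")
        if self.significance < 0:
            raise ValueError("significance must be >= 0")


def significance_from_evalue(evalue: float, cap_exponent: float = 20.0) -> float:
    """Map a blastp e-value to a normalised significance in [0, 1].

    ``min(1, -log10(e) / cap_exponent)``; e-values of 1e-20 or better
    saturate at 1, insignificant hits (e >= 1) score 0.
    """
    if evalue <= 0:
        return 1.0
    return max(0.0, min(1.0, -math.log10(evalue) / cap_exponent))


@dataclass(frozen=True)
class EvidenceBundle:
    introns_supported: int = 0
    exons_supported: int = 0
    homology_hits: tuple[HomologyHit, ...] = ()
    repeat_overlap: bool = False
    te_hit: bool = False

    def __post_init__(self) -> None:
        if self.introns_supported < 0 or self.exons_supported < 0:
            raise ValueError("supported-feature counts must be >= 0")
        object.__setattr__(self, "homology_hits", tuple(self.homology_hits))


@dataclass(frozen=True)
class GeneModelCandidate:
    """A candidate gene model: genomic span, exon structure, evidence."""

    model_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    source: str = ""
    evidence: EvidenceBundle = field(default_factory=EvidenceBundle)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.model_id}: strand must be + or -")
        if self.start > self.end:
            raise ValueError(f"{self.model_id}: start > end")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.model_id}: exon start > end")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.model_id}: exon outside model span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.model_id}: exons overlap or are unsorted")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ScoringConfig:
    """Bonus/penalty magnitudes; only sign and tier ordering are contractual."""

    bonus_per_supported_feature: float = 1.0
    tier_weights: tuple[tuple[str, float], ...] = (
        ("arabidopsis", 10.0), ("swissprot", 5.0), ("nr", 2.0))
    repeat_penalty: float = -100.0
    te_penalty: float = -100.0

    def __post_init__(self) -> None:
        w = dict(self.tier_weights)
        if set(w) != set(TIER_ORDER):
            raise ValueError(f"tier_weights must cover exactly {TIER_ORDER}")
        if not (w["arabidopsis"] > w["swissprot"] > w["nr"] > 0):
            raise ValueError("tier weights must satisfy arabidopsis > swissprot > nr > 0")
        if self.bonus_per_supported_feature <= 0:
            raise ValueError("feature bonus must be positive")
        if self.repeat_penalty >= 0 or self.te_penalty >= 0:
            raise ValueError("repeat/TE penalties must be negative")

    def tier_weight(self, tier: str) -> float:
        return dict(self.tier_weights)[tier]


@dataclass(frozen=True)
class ScoreBreakdown:
    model_id: str
    total: float
    terms: tuple[tuple[str, float], ...]


def score_candidate(candidate: GeneModelCandidate,
                    config: ScoringConfig | None = None) -> ScoreBreakdown:
    """Score a candidate with a per-term breakdown.

    score = feature_bonus * (introns_supported + exons_supported)
          + sum over hits of tier_weight * significance
          + repeat_penalty [if repeat overlap] + te_penalty [if TE hit]
    """
    config = config or ScoringConfig()
    ev = candidate.evidence
    terms: list[tuple[str, float]] = []
    n_feat = ev.introns_supported + ev.exons_supported
    if n_feat:
        terms.append(("rnaseq_support", config.bonus_per_supported_feature * n_feat))
    for hit in ev.homology_hits:
        terms.append((f"homology_{hit.tier}",
                      config.tier_weight(hit.tier) * hit.significance))
    if ev.repeat_overlap:
        terms.append(("repeat_overlap", config.repeat_penalty))
    if ev.te_hit:
        terms.append(("te_hit", config.te_penalty))
    total = sum(v for _, v in terms)
    return ScoreBreakdown(model_id=candidate.model_id, total=total,
                          terms=tuple(terms))


@dataclass(frozen=True)
class Rejection:
    model_id: str
    blocked_by: str


def _overlaps(a: GeneModelCandidate, b: GeneModelCandidate) -> bool:
    return (a.contig == b.contig and a.strand == b.strand
            and a.start <= b.end and b.start <= a.end)


def select_models(candidates: list[GeneModelCandidate],
                  config: ScoringConfig | None = None,
                  scores: dict[str, ScoreBreakdown] | None = None
                  ) -> tuple[list[GeneModelCandidate], list[Rejection]]:
    """Greedy best-first selection of a non-overlapping annotation.

    Candidates are visited in descending score order (ties broken by longer
    span, then lexicographic model id, so selection is input-order
    invariant); a candidate is accepted iff its span overlaps no previously
    accepted model on the same contig and strand. The rejection log names
    the accepted model that blocked each rejected one.
    """
    config = config or ScoringConfig()
    if scores is None:
        scores = {c.model_id: score_candidate(c, config) for c in candidates}
    order = sorted(candidates,
                   key=lambda c: (-scores[c.model_id].total, -c.span_length,
                                  c.model_id))
    accepted: dict[tuple[str, str], list[GeneModelCandidate]] = {}
    selected: list[GeneModelCandidate] = []
    rejections: list[Rejection] = []
    for cand in order:
        key = (cand.contig, cand.strand)
        blocker = next((a for a in accepted.get(key, ())
                        if a.start <= cand.end and cand.start <= a.end), None)
        if blocker is None:
            accepted.setdefault(key, []).append(cand)
            selected.append(cand)
        else:
            rejections.append(Rejection(model_id=cand.model_id,
                                        blocked_by=blocker.model_id))
    return selected, rejections


def selection_report(selected: list[GeneModelCandidate],
                     candidates: list[GeneModelCandidate]) -> dict:
    """Summary metrics of a selection round."""
    per_source: dict[str, int] = {}
    for c in selected:
        per_source[c.source] = per_source.get(c.source, 0) + 1
    n_rna = sum(1 for c in selected
                if c.evidence.introns_supported + c.evidence.exons_supported > 0)
    return {
        "n_candidates": len(candidates),
        "n_selected": len(selected),
        "per_source": dict(sorted(per_source.items())),
        "fraction_rnaseq_supported": n_rna / len(selected) if selected else 0.0,
    }
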