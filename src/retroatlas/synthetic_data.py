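"""Synthetic data generators with recorded ground truth.

Three generators mirror the three input kinds of the pipeline:

* LTR retroelement libraries whose paired long terminal repeats have
  diverged under a two-parameter (transition/transversion) substitution
  process at a known per-year rate, so true insertion ages are known;
* negative-binomial read-count matrices with planted broad-, specific-,
  stable- and silent-expression genes and unequal library sizes;
* pools of overlapping candidate gene models with RNA-seq / homology /
  repeat evidence and a designated dominant-evidence winner per locus.

All randomness flows from one explicit integer seed per call; repeated
calls with the same spec are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_ranker import EvidenceBundle, GeneModelCandidate, HomologyHit
from .ltr_dating import LTRElement, REQUIRED_DOMAINS

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner of A,C,G,T (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion partners of each base
_TRANSVERSION = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)

DEFAULT_RATE = 1.3e-8  # substitutions / site / year
DEFAULT_KAPPA = 2.0


@dataclass(frozen=True)
class EvolutionSpec:
    """Two-parameter substitution process for one branch.

    Parameters
    ----------
    rate_r : substitutions per site per year (> 0).
    kappa : transition/transversion *rate* ratio alpha/beta (> 0).
    age_years : branch duration; expected divergence is ``rate_r * age_years``.
    seed : integer seed controlling every random draw.
    """

    rate_r: float = DEFAULT_RATE
    kappa: float = DEFAULT_KAPPA
    age_years: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate_r > 0:
            raise ValueError(f"rate_r must be > 0, got {self.rate_r}")
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")

    @property
    def divergence(self) -> float:
        """Expected substitutions per site along this branch."""
        d = self.rate_r * self.age_years
        if not math.isfinite(d):
            raise ValueError("rate_r * age_years is not finite")
        return d


def k2p_site_probabilities(d: float, kappa: float) -> tuple[float, float]:
    """Closed-form per-site transition (p) and transversion (q) probabilities.

    Rates are normalised so that one unit of branch length ``d`` equals one
    expected substitution per site: with transition rate ``alpha`` and
    per-target transversion rate ``beta``, ``alpha + 2 beta = 1`` and
    ``alpha / beta = kappa``.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p = 0.25 + 0.25 * math.exp(-4.0 * beta * d) - 0.5 * math.exp(-2.0 * (alpha + beta) * d)
    q = 0.5 - 0.5 * math.exp(-4.0 * beta * d)
    return p, q


def _encode(sequence: str) -> np.ndarray:
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = np.full(raw.shape, 255, dtype=np.uint8)
    for i, b in enumerate(_ALPHABET):
        idx[raw == b] = i
    bad = np.nonzero(idx == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-ACGT character {sequence[pos]!r} at position {pos} (0-based)"
        )
    return idx


def _decode(idx: np.ndarray) -> str:
    return _ALPHABET[idx].tobytes().decode("ascii")


def mutate_sequence_k2p(sequence: str, spec: EvolutionSpec) -> str:
    """Mutate a sequence along one branch of the two-parameter process.

    Each site is substituted independently using the exact closed-form
    transition/transversion probabilities at total branch length
    ``rate_r * age_years`` — no per-generation iteration, so the output
    distribution matches the distance estimator's model exactly.
    """
    idx = _encode(sequence)
    d = spec.divergence
    if d == 0.0 or idx.size == 0:
        return sequence
    p, q = k2p_site_probabilities(d, spec.kappa)
    rng = np.random.default_rng(spec.seed)
    u = rng.random(idx.size)
    pick = rng.integers(0, 2, size=idx.size)
    out = idx.copy()
    ts = u < p
    tv = (u >= p) & (u < p + q)
    out[ts] = _TRANSITION[idx[ts]]
    out[tv] = _TRANSVERSION[idx[tv], pick[tv]]
    return _decode(out)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform ACGT sequence (no GC bias)."""
    return _decode(rng.integers(0, 4, size=length).astype(np.uint8))


def inject_indels(sequence: str, rate: float, rng: np.random.Generator,
                  max_len: int = 3) -> str:
    """Optional per-site indel injector for exercising gap handling.

    At each site, with probability ``rate``, either delete up to ``max_len``
    bases or insert a random segment of up to ``max_len`` bases (equal odds).
    """
    if not 0 <= rate < 1:
        raise ValueError("indel rate must be in [0, 1)")
    out: list[str] = []
    i = 0
    while i < len(sequence):
        if rng.random() < rate:
            size = int(rng.integers(1, max_len + 1))
            if rng.random() < 0.5:
                i += size  # deletion
                continue
            out.append(random_sequence(size, rng))
        out.append(sequence[i])
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# LTR retroelement libraries


def uniform_ages(low: float, high: float):
    """Age sampler: uniform on [low, high] years."""
    if not 0 <= low <= high:
        raise ValueError("need 0 <= low <= high")

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, size=n)

    return sampler


def two_class_ages(recent_fraction: float, threshold: float = 5e5,
                   old_max: float = 5e6):
    """Age sampler planting a known fraction of recent (< threshold) ages.

    Recent ages are uniform on [0, threshold); old ages uniform on
    [threshold, old_max). Used to emulate genome-scale regimes where a known
    share of insertions postdates the recency cutoff.
    """
    if not 0 <= recent_fraction <= 1:
        raise ValueError("recent_fraction must be in [0, 1]")

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        recent = rng.random(n) < recent_fraction
        ages = rng.uniform(threshold, old_max, size=n)
        ages[recent] = rng.uniform(0.0, threshold, size=int(recent.sum()))
        return ages

    return sampler


DEFAULT_FAMILIES = {
    "Athila": 0.4, "Tekay": 0.2, "Ale": 0.1, "SIRE": 0.1,
    "TAR": 0.08, "Ikeros": 0.05, "Tork": 0.04, "CRM": 0.03,
}


def simulate_ltr_pairs(
    n_elements: int,
    ltr_length: int,
    age_sampler,
    spec: EvolutionSpec,
    families: dict[str, float] | None = None,
    complete_fraction: float = 1.0,
    indel_rate: float = 0.0,
) -> tuple[list[LTRElement], pd.DataFrame]:
    """Simulate diverged 5'/3' LTR pairs with known ages (no genome context).

    Each element gets one ancestral LTR; the two copies evolve independently
    for the sampled age, so the expected pairwise divergence is
    ``2 * rate_r * age``. Returns the elements and a truth table with the
    true age per element.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if ltr_length < 50:
        raise ValueError(
            f"ltr_length must be >= 50 for stable frequency estimates, got {ltr_length}"
        )
    fams = dict(families or DEFAULT_FAMILIES)
    labels = list(fams)
    probs = np.asarray([fams[k] for k in labels], dtype=float)
    probs = probs / probs.sum()

    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    ages = np.asarray(age_sampler(rng, n_elements), dtype=float)
    fam_idx = rng.choice(len(labels), size=n_elements, p=probs)
    complete = rng.random(n_elements) < complete_fraction
    child_seeds = ss.spawn(n_elements)

    elements: list[LTRElement] = []
    rows = []
    for i in range(n_elements):
        erng = np.random.default_rng(child_seeds[i])
        ancestor = random_sequence(ltr_length, erng)
        s5, s3 = (int(x) for x in erng.integers(0, 2**31 - 1, size=2))
        branch = EvolutionSpec(rate_r=spec.rate_r, kappa=spec.kappa,
                               age_years=float(ages[i]), seed=s5)
        ltr5 = mutate_sequence_k2p(ancestor, branch)
        branch = EvolutionSpec(rate_r=spec.rate_r, kappa=spec.kappa,
                               age_years=float(ages[i]), seed=s3)
        ltr3 = mutate_sequence_k2p(ancestor, branch)
        if indel_rate > 0:
            ltr5 = inject_indels(ltr5, indel_rate, erng)
            ltr3 = inject_indels(ltr3, indel_rate, erng)
        if complete[i]:
            domains = set(REQUIRED_DOMAINS)
        else:
            missing = erng.choice(sorted(REQUIRED_DOMAINS),
                                  size=int(erng.integers(1, 3)), replace=False)
            domains = set(REQUIRED_DOMAINS) - set(missing)
        eid = f"RTE{i + 1:05d}"
        fam = labels[fam_idx[i]]
        elements.append(LTRElement(element_id=eid, family=fam,
                                   superfamily=_superfamily(fam),
                                   ltr5=ltr5, ltr3=ltr3,
                                   domains_present=domains))
        rows.append({"element_id": eid, "family": fam,
                     "true_age_years": float(ages[i]),
                     "complete": bool(complete[i])})
    truth = pd.DataFrame(rows)
    return elements, truth


_GYPSY = {"Athila", "Tekay", "CRM", "Ogre", "Retand"}


def _superfamily(family: str) -> str:
    return "Ty3/Gypsy" if family in _GYPSY else "Ty1/Copia"


@dataclass
class LTRLibrary:
    """A simulated genome with annotated LTR retroelements."""

    contig_id: str
    genome: str
    features: list  # GFFFeature records
    elements: list
    truth: pd.DataFrame


def simulate_ltr_library(
    n_elements: int,
    ltr_length: int,
    age_sampler,
    spec: EvolutionSpec,
    families: dict[str, float] | None = None,
    complete_fraction: float = 1.0,
    internal_length: int = 300,
    spacer_length: int = 200,
    contig_id: str = "chrSim",
) -> LTRLibrary:
    """Simulate a genome FASTA + element GFF3 + truth table.

    Elements are laid out as ``spacer LTR5 internal LTR3 spacer ...`` on one
    contig; the GFF3 carries an ``LTR_retrotransposon`` feature per element
    with two ``long_terminal_repeat`` children and ``ID``, ``Family``,
    ``Complete`` and ``Domains`` attributes (1-based inclusive coordinates).
    """
    from .io import GFFFeature  # deferred to avoid import cycle

    elements, truth = simulate_ltr_pairs(
        n_elements, ltr_length, age_sampler, spec,
        families=families, complete_fraction=complete_fraction)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5ACE]))

    chunks: list[str] = []
    features: list[GFFFeature] = []
    pos = 0  # 0-based running offset
    for el in elements:
        chunks.append(random_sequence(spacer_length, rng))
        pos += spacer_length
        internal = random_sequence(internal_length, rng)
        start = pos + 1  # 1-based
        l5_end = pos + len(el.ltr5)
        l3_start = pos + len(el.ltr5) + internal_length + 1
        end = l3_start + len(el.ltr3) - 1
        chunks.append(el.ltr5 + internal + el.ltr3)
        pos = end
        row = truth.loc[truth["element_id"] == el.element_id].iloc[0]
        attrs = {
            "ID": el.element_id,
            "Family": el.family,
            "Complete": "true" if row["complete"] else "false",
            "Domains": ",".join(sorted(el.domains_present)),
        }
        features.append(GFFFeature(contig_id, "retroatlas_sim",
                                   "LTR_retrotransposon", start, end, ".",
                                   "+", ".", attrs))
        for j, (s, e) in enumerate(((start, l5_end), (l3_start, end)), 1):
            features.append(GFFFeature(
                contig_id, "retroatlas_sim", "long_terminal_repeat",
                s, e, ".", "+", ".",
                {"ID": f"{el.element_id}_LTR{j}", "Parent": el.element_id}))
    chunks.append(random_sequence(spacer_length, rng))
    genome = "".join(chunks)
    truth = truth.copy()
    return LTRLibrary(contig_id=contig_id, genome=genome, features=features,
                      elements=elements, truth=truth)


# ---------------------------------------------------------------------------
# Count matrices

CLASS_BROAD = "broad"
CLASS_SPECIFIC = "specific"
CLASS_STABLE = "stable"
CLASS_SILENT = "silent"


@dataclass(frozen=True)
class CountSimSpec:
    """Design of a planted-truth negative-binomial count matrix.

    Defaults emulate a 46-sample organ/stage atlas with two biological
    replicates per sample. ``class_fractions`` plant four gene classes:
    ``broad`` (expressed everywhere, sample means jittered log-normally),
    ``specific`` (one expressing sample), ``stable`` (constant mean) and
    ``silent`` (all-zero).
    """

    n_genes: int = 2000
    samples: tuple[str, ...] = tuple(f"S{i + 1:02d}" for i in range(46))
    n_replicates: int = 2
    library_size_factors: tuple[float, ...] | None = None
    dispersion: float = 0.05
    class_fractions: tuple[tuple[str, float], ...] = (
        (CLASS_BROAD, 0.6), (CLASS_SPECIFIC, 0.2),
        (CLASS_STABLE, 0.1), (CLASS_SILENT, 0.1),
    )
    base_mean: float = 100.0
    broad_log_sd: float = 0.4
    factor_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        total = sum(f for _, f in self.class_fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if self.library_size_factors is not None:
            lsf = np.asarray(self.library_size_factors, dtype=float)
            if lsf.shape != (len(self.samples) * self.n_replicates,):
                raise ValueError("library_size_factors must have one entry per column")
            if not (lsf > 0).all():
                raise ValueError("library_size_factors must be positive")

    @property
    def columns(self) -> list[str]:
        return [f"{s}.{r + 1}" for s in self.samples for r in range(self.n_replicates)]


def simulate_count_matrix(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a genes x (sample, replicate) count matrix with planted truth.

    Returns ``(counts, truth)`` where counts is an integer DataFrame indexed
    by gene id with ``SAMPLE.REP`` columns and truth records each gene's
    planted class, its expressing sample (for specific genes) and the true
    per-column library size factors (as attrs on the truth frame and a
    ``truth.attrs['size_factors']`` vector).
    """
    rng = np.random.default_rng(spec.seed)
    n_cols = len(spec.samples) * spec.n_replicates
    if spec.library_size_factors is None:
        lsf = np.exp(rng.normal(0.0, spec.factor_log_sd, size=n_cols))
        lsf /= np.exp(np.mean(np.log(lsf)))  # geometric mean 1
    else:
        lsf = np.asarray(spec.library_size_factors, dtype=float)

    labels = []
    for cls, frac in spec.class_fractions:
        labels.extend([cls] * int(round(frac * spec.n_genes)))
    while len(labels) < spec.n_genes:
        labels.append(spec.class_fractions[0][0])
    labels = labels[: spec.n_genes]
    rng.shuffle(labels)

    n_samples = len(spec.samples)
    mu_samples = np.zeros((spec.n_genes, n_samples))
    specific_sample = np.full(spec.n_genes, "", dtype=object)
    for g, cls in enumerate(labels):
        if cls == CLASS_BROAD:
            mu_samples[g] = spec.base_mean * np.exp(
                rng.normal(0.0, spec.broad_log_sd, size=n_samples))
        elif cls == CLASS_SPECIFIC:
            j = int(rng.integers(0, n_samples))
            mu_samples[g, j] = spec.base_mean * 4.0
            specific_sample[g] = spec.samples[j]
        elif cls == CLASS_STABLE:
            mu_samples[g] = spec.base_mean * 2.0
        # silent: all-zero means

    mu = np.repeat(mu_samples, spec.n_replicates, axis=1) * lsf[None, :]
    size = 1.0 / spec.dispersion
    counts = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    # NB(mean mu, var mu + dispersion mu^2) via gamma-Poisson mixture
    lam = rng.gamma(shape=size, scale=mu[pos] / size)
    counts[pos] = rng.poisson(lam)

    gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    cols = spec.columns
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=cols)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "class": labels,
        "specific_sample": specific_sample,
    }).set_index("gene_id")
    truth.attrs["size_factors"] = pd.Series(lsf, index=cols)
    return counts_df, truth


# ---------------------------------------------------------------------------
# Candidate gene models


@dataclass(frozen=True)
class EvidenceRates:
    """Evidence-assignment probabilities for winners vs decoys.

    Defaults are the dominant-evidence regime: the designated winner carries
    every bonus (RNA-seq supported features, a significant best-tier homology
    hit, no repeat/TE overlap) while decoys carry penalties, so a correct
    ranker must recover every winner.
    """

    winner_rnaseq: float = 1.0
    winner_homology: float = 1.0
    winner_repeat: float = 0.0
    decoy_rnaseq: float = 0.0
    decoy_homology: float = 0.0
    decoy_repeat: float = 1.0

    def __post_init__(self) -> None:
        for name in ("winner_rnaseq", "winner_homology", "winner_repeat",
                     "decoy_rnaseq", "decoy_homology", "decoy_repeat"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ModelSimSpec:
    """Design of an overlapping candidate gene-model pool."""

    n_loci: int = 50
    predictors: tuple[str, ...] = ("augustus_hints", "augustus_ab_initio", "genemark")
    candidates_per_locus: int = 3
    evidence_rates: EvidenceRates = field(default_factory=EvidenceRates)
    locus_spacing: int = 5000
    contig_id: str = "ctgSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.candidates_per_locus < 1:
            raise ValueError("candidates_per_locus must be >= 1")


_TIERS = ("arabidopsis", "swissprot", "nr")


def simulate_gene_model_candidates(
    spec: ModelSimSpec,
) -> tuple[list[GeneModelCandidate], pd.DataFrame]:
    """Simulate overlapping candidates per locus with a designated winner.

    Returns ``(candidates, truth)``; truth marks the intended winner of each
    locus (the candidate given dominant evidence under the configured rates).
    """
    rng = np.random.default_rng(spec.seed)
    rates = spec.evidence_rates
    candidates: list[GeneModelCandidate] = []
    rows = []
    for locus in range(spec.n_loci):
        base = 1 + locus * spec.locus_spacing
        span_len = int(rng.integers(800, 2000))
        n_cand = spec.candidates_per_locus
        winner_idx = int(rng.integers(0, n_cand))
        strand = "+" if rng.random() < 0.5 else "-"
        for c in range(n_cand):
            start = base + int(rng.integers(0, 200))
            end = start + span_len + int(rng.integers(-150, 150))
            n_exons = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(
                np.arange(start, end), size=2 * n_exons, replace=False))
            exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1]))
                     for k in range(n_exons)]
            is_winner = c == winner_idx
            p_rna = rates.winner_rnaseq if is_winner else rates.decoy_rnaseq
            p_hom = rates.winner_homology if is_winner else rates.decoy_homology
            p_rep = rates.winner_repeat if is_winner else rates.decoy_repeat
            supported = int(rng.binomial(n_exons, p_rna))
            hits = []
            if rng.random() < p_hom:
                tier = _TIERS[0] if is_winner else _TIERS[int(rng.integers(0, 3))]
                hits.append(HomologyHit(tier=tier,
                                        significance=float(rng.uniform(0.5, 1.0))))
            repeat_overlap = bool(rng.random() < p_rep)
            te_hit = bool(rng.random() < p_rep)
            mid = f"L{locus + 1:04d}c{c + 1}"
            candidates.append(GeneModelCandidate(
                model_id=mid,
                contig=spec.contig_id,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                source=spec.predictors[c % len(spec.predictors)],
                evidence=EvidenceBundle(
                    introns_supported=max(0, supported - 1),
                    exons_supported=supported,
                    homology_hits=tuple(hits),
                    repeat_overlap=repeat_overlap,
                    te_hit=te_hit,
                ),
            ))
            if is_winner:
                rows.append({"locus": f"L{locus + 1:04d}", "winner": mid})
    truth = pd.DataFrame(rows)
    return candidates, truth
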