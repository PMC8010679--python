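"""Readers and writers for the interchange formats (FASTA, GFF3, TSV, newick).

Coordinates are GFF3-style 1-based inclusive throughout. All table writers
can prepend a provenance header (``# key: value`` comment lines) so CLI
outputs record the version, configuration hash and seeds that produced
them; the readers skip such lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

import pandas as pd

from .annotation_ranker import (EvidenceBundle, GeneModelCandidate,
                                HomologyHit)
from .ltr_dating import LTRElement, REQUIRED_DOMAINS

logger = logging.getLogger(__name__)

_KNOWN_FEATURE_TYPES = {
    "LTR_retrotransposon", "long_terminal_repeat",
    "gene", "mRNA", "exon", "CDS", "intron", "region",
}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Rejects duplicate identifiers, empty headers, and sequence data that
    appears before any header (reported with its line number).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                break
            raise ValueError(
                f"{path}:{lineno}: sequence data before any '>' header")
    from Bio import SeqIO

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path) -> None:
    """Write sequences as FASTA with 60-column line wrap."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


# ---------------------------------------------------------------------------
# GFF3


@dataclass(frozen=True)
class GFFFeature:
    """One GFF3 feature line (1-based inclusive coordinates)."""

    seqid: str
    source: str
    featuretype: str
    start: int
    end: int
    score: str = "."
    strand: str = "."
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid span {self.start}..{self.end} for feature "
                f"{self.attributes.get('ID', '?')}")

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")


def _encode_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    safe = ":,.()- "
    return ";".join(f"{quote(k, safe=safe)}={quote(str(v), safe=safe)}"
                    for k, v in attrs.items())


def read_gff3(path, validate: bool = True) -> list[GFFFeature]:
    """Parse a GFF3 file into typed features with validated linkage.

    Raises on reversed spans and (when ``validate``) on children lying
    outside their parent's span or strandless LTR elements; unknown feature
    types are passed through with a logged warning.
    """
    import gffutils.iterators

    path = Path(path)
    features: list[GFFFeature] = []
    for f in gffutils.iterators.DataIterator(str(path)):
        if f.end < f.start:
            raise ValueError(
                f"{path}: feature {f.id or '?'} has end < start ({f.end} < {f.start})")
        attrs = {k: ",".join(unquote(v) for v in vals)
                 for k, vals in f.attributes.items()}
        feat = GFFFeature(seqid=f.seqid, source=f.source,
                          featuretype=f.featuretype, start=f.start, end=f.end,
                          score=f.score, strand=f.strand, phase=f.frame,
                          attributes=attrs)
        if feat.featuretype not in _KNOWN_FEATURE_TYPES:
            logger.warning("%s: unknown feature type %r passed through",
                           path, feat.featuretype)
        features.append(feat)
    if validate:
        validate_gff_features(features, str(path))
    return features


def validate_gff_features(features: list[GFFFeature], origin: str = "<gff>") -> None:
    by_id = {f.feature_id: f for f in features if f.feature_id}
    for f in features:
        if f.featuretype == "LTR_retrotransposon" and f.strand not in "+-":
            raise ValueError(
                f"{origin}: LTR_retrotransposon {f.feature_id or '?'} needs an "
                f"explicit strand, got {f.strand!r}")
        if f.parent:
            parent = by_id.get(f.parent)
            if parent is None:
                raise ValueError(f"{origin}: {f.feature_id or '?'} references "
                                 f"unknown parent {f.parent!r}")
            if f.start < parent.start or f.end > parent.end:
                raise ValueError(
                    f"{origin}: child {f.feature_id or '?'} "
                    f"({f.start}..{f.end}) lies outside parent {f.parent} "
                    f"span ({parent.start}..{parent.end})")


def write_gff3(features: list[GFFFeature], path,
               provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, v in (provenance or {}).items():
            fh.write(f"#{k}: {v}\n")
        for f in features:
            fh.write("\t".join([
                f.seqid, f.source, f.featuretype, str(f.start), str(f.end),
                f.score, f.strand, f.phase, _encode_attrs(f.attributes),
            ]) + "\n")


# ---------------------------------------------------------------------------
# GFF3 <-> domain objects


def ltr_elements_from_gff(features: list[GFFFeature],
                          sequences: dict[str, str]) -> list[LTRElement]:
    """Assemble LTRElement records from element/LTR features plus genome FASTA.

    LTR sequences are extracted on the annotated strand and
    reverse-complemented to forward element orientation for minus-strand
    elements. Domain completeness comes from the ``Domains`` attribute
    (comma-separated labels) or, failing that, ``Complete=true`` implies all
    five required domains.
    """
    children: dict[str, list[GFFFeature]] = {}
    for f in features:
        if f.featuretype == "long_terminal_repeat" and f.parent:
            children.setdefault(f.parent, []).append(f)
    elements: list[LTRElement] = []
    for f in features:
        if f.featuretype != "LTR_retrotransposon":
            continue
        eid = f.feature_id or f"{f.seqid}:{f.start}-{f.end}"
        ltrs = sorted(children.get(eid, []), key=lambda c: c.start)
        if len(ltrs) != 2:
            raise ValueError(f"element {eid} needs exactly 2 long_terminal_repeat "
                             f"children, found {len(ltrs)}")
        if f.seqid not in sequences:
            raise ValueError(f"element {eid}: contig {f.seqid!r} absent from FASTA")
        contig = sequences[f.seqid]
        if f.end > len(contig):
            raise ValueError(f"element {eid} extends past the end of {f.seqid}")
        seqs = [contig[c.start - 1:c.end] for c in ltrs]
        if f.strand == "-":
            seqs = [reverse_complement(s) for s in reversed(seqs)]
        if "Domains" in f.attributes and f.attributes["Domains"]:
            domains = frozenset(f.attributes["Domains"].split(","))
        elif f.attributes.get("Complete", "").lower() == "true":
            domains = REQUIRED_DOMAINS
        else:
            domains = frozenset()
        elements.append(LTRElement(
            element_id=eid,
            family=f.attributes.get("Family", "unclassified"),
            superfamily=f.attributes.get("Superfamily", ""),
            ltr5=seqs[0], ltr3=seqs[1], domains_present=domains))
    return elements


def _bool_attr(attrs: dict[str, str], key: str) -> bool:
    return attrs.get(key, "false").lower() in {"true", "1", "yes"}


def gene_models_from_gff(features: list[GFFFeature]) -> list[GeneModelCandidate]:
    """Assemble candidate gene models from mRNA features with evidence attrs.

    Evidence attributes: ``introns_supported``, ``exons_supported``
    (integers), ``homology_hits`` as a comma-separated ``tier:score`` list,
    ``repeat_overlap`` / ``te_hit`` booleans; ``exon`` children give the
    exon structure.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.featuretype == "exon" and f.parent:
            exons.setdefault(f.parent, []).append((f.start, f.end))
    candidates: list[GeneModelCandidate] = []
    for f in features:
        if f.featuretype != "mRNA":
            continue
        mid = f.feature_id or f"{f.seqid}:{f.start}-{f.end}"
        hits = []
        raw = f.attributes.get("homology_hits", "")
        if raw:
            for item in raw.split(","):
                tier, _, score = item.partition(":")
                hits.append(HomologyHit(tier=tier.strip(),
                                        significance=float(score)))
        ev = EvidenceBundle(
            introns_supported=int(f.attributes.get("introns_supported", 0)),
            exons_supported=int(f.attributes.get("exons_supported", 0)),
            homology_hits=tuple(hits),
            repeat_overlap=_bool_attr(f.attributes, "repeat_overlap"),
            te_hit=_bool_attr(f.attributes, "te_hit"),
        )
        candidates.append(GeneModelCandidate(
            model_id=mid, contig=f.seqid, strand=f.strand,
            start=f.start, end=f.end,
            exons=tuple(sorted(exons.get(mid, []))),
            source=f.source, evidence=ev))
    return candidates


def gene_models_to_gff(candidates: list[GeneModelCandidate]) -> list[GFFFeature]:
    """Serialise candidates as mRNA + exon features with evidence attributes."""
    features: list[GFFFeature] = []
    for c in candidates:
        attrs = {
            "ID": c.model_id,
            "introns_supported": str(c.evidence.introns_supported),
            "exons_supported": str(c.evidence.exons_supported),
            "repeat_overlap": "true" if c.evidence.repeat_overlap else "false",
            "te_hit": "true" if c.evidence.te_hit else "false",
        }
        if c.evidence.homology_hits:
            attrs["homology_hits"] = ",".join(
                f"{h.tier}:{h.significance!r}" for h in c.evidence.homology_hits)
        features.append(GFFFeature(c.contig, c.source or "retroatlas", "mRNA",
                                   c.start, c.end, ".", c.strand, ".", attrs))
        for i, (s, e) in enumerate(c.exons, 1):
            features.append(GFFFeature(
                c.contig, c.source or "retroatlas", "exon", s, e, ".",
                c.strand, ".", {"ID": f"{c.model_id}.exon{i}",
                                "Parent": c.model_id}))
    return features


# ---------------------------------------------------------------------------
# Tables


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a gene x SAMPLE.REP integer count table (TSV, '#' comments).

    The first column is the gene id; every other column label must be of the
    form ``SAMPLE.REP``. Non-integer or negative cells are rejected with the
    offending gene and column named.
    """
    from .expression_atlas import split_columns

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene id column plus count columns")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    split_columns(df.columns)  # raises on malformed SAMPLE.REP labels
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() | (series != series.round())
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-integer count for gene {gene!r} in column {col!r}")
        if (series < 0).any():
            gene = df.index[(series < 0).to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: negative count for gene {gene!r} in column {col!r}")
    return df.astype("int64")


def write_table(df: pd.DataFrame, path, provenance: dict | None = None,
                index: bool = True) -> None:
    """Write a DataFrame as TSV with optional '# key: value' provenance lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", comment="#", **kwargs)
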