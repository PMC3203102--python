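"""Variant effect annotation against a toy gene model.

Effects follow the categories an exome study reports: coding changes
(synonymous, non-synonymous, nonsense — and frameshift / in-frame for
indels), splice-site (within a configurable window, default 2 bp, into the
intron at each exon boundary), 5'/3' UTR, "near gene" (within 50 bp
upstream of a transcript start, strand-aware), microRNA, intronic and
intergenic.  When a variant hits several transcripts the most severe
effect wins, with the severity order fixed below.  Novelty is membership
in a known-sites set (the dbSNP / 1000 Genomes surrogate).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

SEVERITY_ORDER = (
    "nonsense", "frameshift", "splice-site", "non-synonymous", "inframe_indel",
    "synonymous", "utr5", "utr3", "near_gene", "microRNA", "intronic",
    "intergenic",
)
_SEVERITY = {e: i for i, e in enumerate(SEVERITY_ORDER)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Transcript:
    """A protein-coding transcript; all intervals 0-based half-open, genomic."""

    name: str
    chrom: str
    strand: str  # "+" or "-"
    start: int
    end: int
    exons: tuple  # ((start, end), ...) sorted, non-overlapping
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError(f"exons of {self.name} must be sorted and non-overlapping")
            prev_end = e
        if not (self.start <= self.cds_start < self.cds_end <= self.end):
            raise ValueError(f"CDS of {self.name} must lie within the transcript")
        if len(self.cds_positions()) % 3 != 0:
            raise ValueError(f"CDS length of {self.name} must be divisible by 3")

    def cds_positions(self) -> list[int]:
        """Genomic 0-based positions of CDS bases, ascending."""
        pos = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                pos.extend(range(lo, hi))
        return pos


@dataclass
class GeneModel:
    """Transcripts plus microRNA intervals, with annotation windows."""

    transcripts: list[Transcript] = field(default_factory=list)
    mirnas: list[tuple] = field(default_factory=list)  # (chrom, start, end, name)
    splice_window: int = 2
    near_gene_bp: int = 50

    def __post_init__(self) -> None:
        self._tree: dict[str, IntervalTree] = {}
        self._mirna_tree: dict[str, IntervalTree] = {}
        pad = self.near_gene_bp
        for t in self.transcripts:
            self._tree.setdefault(t.chrom, IntervalTree()).addi(
                t.start - pad, t.end + pad, t)
        for chrom, s, e, name in self.mirnas:
            self._mirna_tree.setdefault(chrom, IntervalTree()).addi(s, e, name)

    def transcripts_near(self, chrom: str, pos0: int) -> list[Transcript]:
        tree = self._tree.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos0]), key=lambda t: t.name)

    def in_mirna(self, chrom: str, pos0: int) -> bool:
        tree = self._mirna_tree.get(chrom)
        return bool(tree is not None and tree[pos0])


@dataclass(frozen=True)
class EffectAnnotation:
    key: tuple
    effect: str
    amino_acid_change: Optional[tuple] = None  # (ref_aa, codon_number, alt_aa)

    def __post_init__(self) -> None:
        if self.effect not in _SEVERITY:
            raise ValueError(f"unknown effect {self.effect!r}")


def _coding_effect(tx: Transcript, pos0: int, ref: str, alt: str,
                   reference) -> tuple[str, tuple]:
    cds = tx.cds_positions()
    i = bisect.bisect_left(cds, pos0)
    coding_idx = i if tx.strand == "+" else len(cds) - 1 - i
    codon_number = coding_idx // 3
    offset = coding_idx % 3
    if tx.strand == "+":
        codon_pos = cds[codon_number * 3: codon_number * 3 + 3]
    else:
        rev = cds[::-1]
        codon_pos = rev[codon_number * 3: codon_number * 3 + 3]
    bases = [reference.get_base(tx.chrom, p + 1) for p in codon_pos]
    alt_bases = list(bases)
    alt_bases[offset] = alt
    if tx.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_bases = [b.translate(_COMPLEMENT) for b in alt_bases]
    ref_aa = str(Seq("".join(bases)).translate())
    alt_aa = str(Seq("".join(alt_bases)).translate())
    if alt_aa == "*" and ref_aa != "*":
        effect = "nonsense"
    elif alt_aa == ref_aa:
        effect = "synonymous"
    else:
        effect = "non-synonymous"
    return effect, (ref_aa, codon_number + 1, alt_aa)


def _positional_effect(tx: Transcript, pos0: int, splice_window: int,
                       near_gene_bp: int) -> Optional[str]:
    """Non-coding positional category of pos0 relative to one transcript."""
    if tx.start <= pos0 < tx.end:
        in_exon = any(s <= pos0 < e for s, e in tx.exons)
        if in_exon:
            if tx.cds_start <= pos0 < tx.cds_end:
                return "cds"
            before_cds = pos0 < tx.cds_start
            if tx.strand == "+":
                return "utr5" if before_cds else "utr3"
            return "utr3" if before_cds else "utr5"
        for s, e in tx.exons:
            # intronic side of each exon boundary
            if s - splice_window <= pos0 < s or e <= pos0 < e + splice_window:
                return "splice-site"
        return "intronic"
    if tx.strand == "+" and tx.start - near_gene_bp <= pos0 < tx.start:
        return "near_gene"
    if tx.strand == "-" and tx.end <= pos0 < tx.end + near_gene_bp:
        return "near_gene"
    return None


def _collapse(effects: Iterable[tuple]) -> tuple:
    """Pick the most severe (effect, aa_change) pair."""
    best = None
    for eff in effects:
        if best is None or _SEVERITY[eff[0]] < _SEVERITY[best[0]]:
            best = eff
    return best if best is not None else ("intergenic", None)


def annotate_snv(variant, model: GeneModel, reference) -> EffectAnnotation:
    """Annotate a single-nucleotide variant.

    ``variant`` is a key tuple (chrom, pos, ref, alt) or a mapping with
    those entries; ``reference`` provides ``get_base(chrom, pos1)``.
    """
    chrom, pos, ref, alt = _as_key(variant)
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("annotate_snv expects a single-base substitution")
    ref_base = reference.get_base(chrom, pos)
    if ref_base != "N" and ref_base != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref!r}, found {ref_base!r}")
    pos0 = pos - 1
    effects = []
    for tx in model.transcripts_near(chrom, pos0):
        cat = _positional_effect(tx, pos0, model.splice_window, model.near_gene_bp)
        if cat == "cds":
            effects.append(_coding_effect(tx, pos0, ref, alt, reference))
        elif cat is not None:
            effects.append((cat, None))
    if model.in_mirna(chrom, pos0):
        effects.append(("microRNA", None))
    effect, aa = _collapse(effects)
    return EffectAnnotation((chrom, pos, ref, alt), effect, aa)


def annotate_indel(variant, model: GeneModel) -> EffectAnnotation:
    """Annotate an insertion or deletion (VCF-style anchored alleles).

    A CDS-overlapping indel is frameshift when its length is not a multiple
    of 3, otherwise in-frame; elsewhere the positional categories apply.
    """
    chrom, pos, ref, alt = _as_key(variant)
    length = abs(len(alt) - len(ref))
    if length == 0:
        raise ValueError("zero-length indel")
    pos0 = pos - 1
    # First affected base: after the anchor for a deletion, the insertion
    # point itself for an insertion.
    probe = pos0 + 1 if len(ref) > len(alt) else pos0
    span = range(pos0 + 1, pos0 + len(ref)) if len(ref) > len(alt) else (probe,)
    effects = []
    for tx in model.transcripts_near(chrom, probe):
        in_cds = any(
            tx.cds_start <= p < tx.cds_end and any(s <= p < e for s, e in tx.exons)
            for p in span)
        if in_cds:
            effects.append(("frameshift" if length % 3 else "inframe_indel", None))
            continue
        cat = _positional_effect(tx, probe, model.splice_window, model.near_gene_bp)
        if cat == "cds":  # probe in CDS but span logic missed (insertion at boundary)
            effects.append(("frameshift" if length % 3 else "inframe_indel", None))
        elif cat is not None:
            effects.append((cat, None))
    if model.in_mirna(chrom, probe):
        effects.append(("microRNA", None))
    effect, aa = _collapse(effects)
    return EffectAnnotation((chrom, pos, ref, alt), effect, aa)


def is_novel(key: tuple, known_sites: set, position_only: bool = False) -> bool:
    """True iff the variant is absent from the known-sites set."""
    if position_only:
        return (key[0], key[1]) not in {(k[0], k[1]) for k in known_sites}
    return key not in known_sites


def _as_key(variant) -> tuple:
    if isinstance(variant, dict):
        return (variant["chrom"], int(variant["pos"]), variant["ref"], variant["alt"])
    chrom, pos, ref, alt = variant
    return (chrom, int(pos), ref, alt)


def read_gff3(path) -> GeneModel:
    """Build a :class:`GeneModel` from a GFF3 file (gene/mRNA/exon/CDS/miRNA).

    Coordinates in GFF3 are 1-based inclusive and converted here to 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    transcripts, mirnas = [], []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons or not cds:
            continue
        transcripts.append(Transcript(
            name=mrna.id, chrom=mrna.seqid, strand=mrna.strand,
            start=mrna.start - 1, end=mrna.end, exons=tuple(exons),
            cds_start=cds[0][0], cds_end=cds[-1][1]))
    for mir in db.features_of_type("miRNA"):
        mirnas.append((mir.seqid, mir.start - 1, mir.end, mir.id))
    return GeneModel(transcripts=transcripts, mirnas=mirnas)


def toy_gene_model(targets: Sequence, splice_window: int = 2,
                   near_gene_bp: int = 50) -> GeneModel:
    """Deterministic toy gene model over simulated capture regions.

    Regions of >= 600 bp get a two-exon transcript with 5'/3' UTRs and a
    CDS whose length is divisible by 3; strand alternates region by region;
    every fifth region instead carries a microRNA interval.  Shorter
    regions are left intergenic.
    """
    transcripts, mirnas = [], []
    for i, t in enumerate(targets):
        L = t.end - t.start
        if i % 5 == 4:
            if L >= 120:
                mirnas.append((t.chrom, t.start + 20, t.start + min(L - 20, 120),
                               f"mir{i}"))
            continue
        if L < 600:
            continue
        s = t.start
        exon1 = (s + 50, s + 50 + (L - 100) * 2 // 5)
        exon2 = (s + 50 + (L - 100) * 3 // 5, s + L - 50)
        cds_start = exon1[0] + 30
        # choose cds_end inside exon2 so the spliced CDS length is % 3 == 0
        cds_len_part1 = exon1[1] - cds_start
        max_part2 = (exon2[1] - 30) - exon2[0]
        part2 = max_part2 - ((cds_len_part1 + max_part2) % 3)
        cds_end = exon2[0] + part2
        transcripts.append(Transcript(
            name=f"tx{i}", chrom=t.chrom, strand="+" if i % 2 == 0 else "-",
            start=exon1[0], end=exon2[1], exons=(exon1, exon2),
            cds_start=cds_start, cds_end=cds_end))
    return GeneModel(transcripts=transcripts, mirnas=mirnas,
                     splice_window=splice_window, near_gene_bp=near_gene_bp)
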