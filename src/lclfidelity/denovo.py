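"""Family- and database-based classification of post-rescue discordant variants.

A discordant variant that survives rescue is a de novo candidate only when
it is carried by exactly one sample-source across the whole family, that
source is the LCL, and the variant is absent from the known-sites set (the
dbSNP / 1000 Genomes surrogate).  Everything else — multi-carrier keys and
known singletons — is classified ``shared_or_known``: a segregating variant
or database-known site, not a culture-acquired mutation.

Also here: Mendelian-violation detection against both parents, the
strand-literal 12-class substitution spectrum, and the selection of
Sanger-validation candidates (LCL-only, no family inheritance pattern,
protein-altering annotation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .config import SUBSTITUTION_TYPES
from .genotyper import CallSet

VALIDATION_EFFECTS = frozenset({"non-synonymous", "splice-site", "nonsense"})

_ALLELES = {"hom-ref": (0, 0), "het": (0, 1), "hom-alt": (1, 1)}


@dataclass(frozen=True)
class DiscordantClassification:
    key: tuple
    carriers: tuple  # ((sample_id, source), ...)
    known_flag: bool
    category: str  # "shared_or_known" | "de_novo_candidate"


@dataclass(frozen=True)
class MendelianViolation:
    child_id: str
    key: tuple
    child_genotype: str
    father_genotype: str
    mother_genotype: str


@dataclass
class SubstitutionSpectrum:
    """Counts over the 12 ordered ref>alt substitution types (strand-literal)."""

    counts: dict[str, int]

    @classmethod
    def empty(cls) -> "SubstitutionSpectrum":
        return cls({t: 0 for t in SUBSTITUTION_TYPES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: (v / t if t else 0.0) for k, v in self.counts.items()}


def classify_discordant(remaining: Iterable[tuple],
                        all_callsets: Sequence[CallSet],
                        known_sites: set,
                        position_only_known: bool = False,
                        ) -> list[DiscordantClassification]:
    """Classify post-rescue discordant keys by carrier structure and novelty.

    ``all_callsets`` are the eight per-sample-source call sets of the
    tetrad; carriers of each key are enumerated across all of them.
    """
    keysets = [(cs.sample_id, cs.source, cs.keys()) for cs in all_callsets]
    if position_only_known:
        known_positions = {(k[0], k[1]) for k in known_sites}
    out = []
    for key in sorted(set(remaining)):
        carriers = tuple((sid, src) for sid, src, ks in keysets if key in ks)
        if not carriers:
            raise ValueError(f"discordant key {key} absent from every call set")
        known = ((key[0], key[1]) in known_positions if position_only_known
                 else key in known_sites)
        is_de_novo = (len(carriers) == 1 and carriers[0][1] == "LCL" and not known)
        out.append(DiscordantClassification(
            key, carriers, known,
            "de_novo_candidate" if is_de_novo else "shared_or_known"))
    return out


def mendelian_check(child: CallSet, father: CallSet, mother: CallSet,
                    treat_missing_as_hom_ref: bool = True,
                    parent_depths: Optional[Mapping[tuple, int]] = None,
                    min_parent_depth: int = 8) -> list[MendelianViolation]:
    """Find sites where the child's genotype cannot be composed of one
    paternal and one maternal allele.

    A sample without a call at a key is treated as hom-ref.  With
    ``parent_depths`` supplied ((sample_id, chrom, pos) -> depth), a site is
    only checked when both parents have depth >= ``min_parent_depth`` there,
    so parental no-calls caused by missing coverage are not over-interpreted.
    """
    if not treat_missing_as_hom_ref:
        raise NotImplementedError("only the hom-ref imputation mode is implemented")
    cg, fg, mg = child.genotypes(), father.genotypes(), mother.genotypes()
    violations = []
    for key in sorted(set(cg) | set(fg) | set(mg)):
        c = cg.get(key, "hom-ref")
        f = fg.get(key, "hom-ref")
        m = mg.get(key, "hom-ref")
        if parent_depths is not None:
            site = (key[0], key[1])
            if parent_depths.get((father.sample_id, *site), 0) < min_parent_depth or \
               parent_depths.get((mother.sample_id, *site), 0) < min_parent_depth:
                continue
        ca, fa, ma = _ALLELES[c], _ALLELES[f], _ALLELES[m]
        consistent = any(sorted((x, y)) == list(ca) for x in fa for y in ma)
        if not consistent:
            violations.append(MendelianViolation(child.sample_id, key, c, f, m))
    return violations


def substitution_spectrum(variants: Iterable) -> SubstitutionSpectrum:
    """Tally SNVs into the 12 ordered ref>alt classes.

    ``variants`` yields (ref, alt) pairs, variant keys (chrom, pos, ref,
    alt), or call-record mappings with "ref"/"alt" entries.  Non-SNV input
    raises.
    """
    spec = SubstitutionSpectrum.empty()
    for v in variants:
        if isinstance(v, Mapping):
            ref, alt = v["ref"], v["alt"]
        elif len(v) == 4:
            ref, alt = v[2], v[3]
        else:
            ref, alt = v
        t = f"{ref}>{alt}"
        if t not in spec.counts:
            raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
        spec.counts[t] += 1
    return spec


def select_validation_candidates(candidates: Sequence[DiscordantClassification],
                                 annotations: Mapping[tuple, str],
                                 children: Optional[Sequence[str]] = None,
                                 ) -> list[tuple]:
    """Shortlist de novo candidates for Sanger validation.

    Keeps keys that (1) are LCL-only single carriers (re-verified from the
    classification, which already implies no family inheritance pattern),
    (2) — when ``children`` is given — are carried by a child, and (3) are
    annotated as protein-altering (non-synonymous, splice-site or nonsense).
    Returned in (chrom, pos) order.
    """
    selected = []
    for c in candidates:
        if c.category != "de_novo_candidate":
            continue
        if not (len(c.carriers) == 1 and c.carriers[0][1] == "LCL"):
            continue  # defensive re-verification of the single-LCL-carrier rule
        if children is not None and c.carriers[0][0] not in children:
            continue
        if c.key not in annotations:
            raise ValueError(f"no annotation for candidate {c.key}")
        if annotations[c.key] not in VALIDATION_EFFECTS:
            continue
        selected.append(c.key)
    return sorted(selected, key=lambda k: (k[0], k[1]))
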