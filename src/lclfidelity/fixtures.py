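"""Deterministic worked-example fixture for the discordance accounting.

Constructs eight small call sets (4 individuals x PBMC/LCL) plus a
known-sites set whose pooled post-rescue discordant pool has a prescribed
composition: a configurable total number of discordant variant keys, of
which a given number are multi-carrier and database-known (segregating or
known variants) and the remainder are single-LCL-carrier novel keys (de
novo candidates).  Defaults reproduce the published accounting of a
tetrad LCL/PBMC exome comparison: 183 pooled discordant variants, 104
multi-carrier/known, 79 single-LCL novel.

Substitution types among the single-LCL novel keys are laid out so that
C>T is the most common class (20/79, ~25%), with the remaining classes
represented as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import SUBSTITUTION_TYPES
from .genotyper import CALL_COLUMNS, CallSet
from .simulate import Pedigree

_CHROM = "chr1"

# 12-class layout of the 79 single-LCL novel keys: C>T dominant (~25%).
_DE_NOVO_TYPE_COUNTS = {
    "C>T": 20, "A>G": 6, "G>A": 6, "T>C": 6, "C>A": 6,
    "A>C": 5, "A>T": 5, "C>G": 5, "G>C": 5, "G>T": 5, "T>A": 5, "T>G": 5,
}


@dataclass
class AccountingFixture:
    pedigree: Pedigree
    callsets: list[CallSet]
    known_sites: set
    discordant_keys: set
    multi_or_known_keys: set
    single_lcl_novel_keys: set

    @property
    def contigs(self) -> dict[str, int]:
        return {_CHROM: 10_000_000}


def _call_row(key: tuple) -> dict:
    chrom, pos, ref, alt = key
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "genotype": "het",
        "depth": 100, "alt_fraction": 0.5, "alt_forward": 25, "alt_reverse": 25,
        "genotype_posterior": 1.0, "tier": "high", "variant_class": "snv",
    }


def paper_accounting_fixture(total: int = 183,
                             multi_or_known: int = 104) -> AccountingFixture:
    """Build the deterministic accounting fixture (see module docstring)."""
    if not (0 <= multi_or_known <= total):
        raise ValueError("multi_or_known must lie in [0, total]")
    n_single = total - multi_or_known
    pedigree = Pedigree.tetrad()
    samples = pedigree.sample_ids

    # Substitution types for the single-LCL novel keys.
    if n_single == 79:
        single_types = [t for t, c in _DE_NOVO_TYPE_COUNTS.items() for _ in range(c)]
    else:
        single_types = [SUBSTITUTION_TYPES[i % 12] for i in range(n_single)]
    shared_types = [SUBSTITUTION_TYPES[i % 12] for i in range(multi_or_known)]

    pairs = [(a, b) for i, a in enumerate(samples) for b in samples[i + 1:]]
    calls: dict[tuple, list] = {(s, src): [] for s in samples for src in ("PBMC", "LCL")}
    known, multi_keys, single_keys = set(), set(), set()

    pos = 1001
    for i, t in enumerate(shared_types):
        ref, alt = t.split(">")
        key = (_CHROM, pos, ref, alt)
        for s in pairs[i % len(pairs)]:
            calls[(s, "LCL")].append(_call_row(key))
        known.add(key)
        multi_keys.add(key)
        pos += 10
    for i, t in enumerate(single_types):
        ref, alt = t.split(">")
        key = (_CHROM, pos, ref, alt)
        calls[(samples[i % 4], "LCL")].append(_call_row(key))
        single_keys.add(key)
        pos += 10

    callsets = []
    for s in samples:
        for src in ("PBMC", "LCL"):
            rows = calls[(s, src)]
            df = (pd.DataFrame(rows, columns=list(CALL_COLUMNS)) if rows else
                  pd.DataFrame({c: pd.Series(dtype=object) for c in CALL_COLUMNS}))
            callsets.append(CallSet(s, src, "high", df))

    return AccountingFixture(
        pedigree=pedigree, callsets=callsets, known_sites=known,
        discordant_keys=multi_keys | single_keys,
        multi_or_known_keys=multi_keys, single_lcl_novel_keys=single_keys)
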