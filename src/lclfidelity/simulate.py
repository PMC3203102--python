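"""Synthetic tetrad-exome generator.

Simulates the inputs of a paired-source exome study: a two-parent/two-child
family in which every individual contributes DNA from two sources — PBMC
(peripheral blood mononuclear cells) and an EBV-transformed lymphoblastoid
cell line (LCL).  Population variants segregate in the family under
Hardy-Weinberg equilibrium and Mendelian transmission and are identical
between the two sources of an individual; each LCL additionally carries a
small number of planted heterozygous de novo mutations emulating variants
acquired during transformation or culturing.

Per-site read pileups are drawn with Poisson depth, per-read miscalls at a
configurable error rate, Bernoulli strand assignment, and two-point base /
mapping quality distributions.  Everything is deterministic given the
configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import BASES, SimulationConfig

SOURCES = ("PBMC", "LCL")

# Fixed tags deriving independent per-stage random streams from the master seed.
_TAG_TARGETS = 1
_TAG_REFERENCE = 2
_TAG_TRUTH = 3
_TAG_DENOVO = 4
_TAG_PILEUPS = 5

PILEUP_COLUMNS = (
    ["chrom", "pos", "sample", "source", "ref"]
    + [f"{b}_fwd" for b in BASES]
    + [f"{b}_rev" for b in BASES]
    + [f"{b}_bq" for b in BASES]
    + ["mq"]
)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
# For each base index, the indices of the three other bases.
_OTHERS = np.array([[j for j in range(4) if j != i] for i in range(4)])


def _stage_rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


@dataclass(frozen=True)
class TargetRegion:
    """A captured interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/inverted region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "1" male, "2" female


@dataclass(frozen=True)
class Pedigree:
    """A tetrad: two founders and two full siblings."""

    members: tuple[PedigreeMember, ...]

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise ValueError("pedigree must have exactly 4 members")
        founders = [m for m in self.members if m.father_id is None and m.mother_id is None]
        children = [m for m in self.members if m.father_id is not None and m.mother_id is not None]
        if len(founders) != 2 or len(children) != 2:
            raise ValueError("pedigree must be 2 founders + 2 children")
        fids = {m.sample_id for m in founders}
        for c in children:
            if {c.father_id, c.mother_id} != fids:
                raise ValueError("both children must reference both founders")

    @classmethod
    def tetrad(cls) -> "Pedigree":
        return cls((
            PedigreeMember("father", None, None, "1"),
            PedigreeMember("mother", None, None, "2"),
            PedigreeMember("child1", "father", "mother", "1"),
            PedigreeMember("child2", "father", "mother", "2"),
        ))

    @property
    def father(self) -> str:
        return next(m.sample_id for m in self.members
                    if m.father_id is None and m.sex == "1")

    @property
    def mother(self) -> str:
        return next(m.sample_id for m in self.members
                    if m.father_id is None and m.sex == "2")

    @property
    def children(self) -> tuple[str, str]:
        return tuple(m.sample_id for m in self.members if m.father_id is not None)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.sample_id for m in self.members)


class SyntheticReference:
    """Deterministic i.i.d.-uniform ACGT reference over the target regions.

    Sequence is generated lazily per region from the master seed; positions
    outside any target read as ``N``.  A FASTA-backed accessor with the same
    two-method interface (``get_base``/``get_seq``) may be used instead.
    """

    def __init__(self, targets: Sequence[TargetRegion], seed: int):
        self.targets = list(targets)
        self.seed = int(seed)
        self._starts = np.array([t.start for t in self.targets], dtype=np.int64)
        self._ends = np.array([t.end for t in self.targets], dtype=np.int64)
        self._cache: dict[int, np.ndarray] = {}

    def _region_codes(self, idx: int) -> np.ndarray:
        if idx not in self._cache:
            t = self.targets[idx]
            rng = _stage_rng(self.seed, _TAG_REFERENCE, idx)
            self._cache[idx] = rng.integers(0, 4, len(t)).astype(np.uint8)
        return self._cache[idx]

    def _region_seq(self, idx: int) -> str:
        return "".join(BASES[c] for c in self._region_codes(idx))

    def _region_index(self, pos0: int) -> Optional[int]:
        i = int(np.searchsorted(self._starts, pos0, side="right")) - 1
        if i >= 0 and self._starts[i] <= pos0 < self._ends[i]:
            return i
        return None

    def get_base(self, chrom: str, pos1: int) -> str:
        i = self._region_index(pos1 - 1)
        if i is None:
            return "N"
        return BASES[self._region_codes(i)[pos1 - 1 - self.targets[i].start]]

    def get_seq(self, chrom: str, start0: int, end0: int) -> str:
        return "".join(self.get_base(chrom, p + 1) for p in range(start0, end0))


class DictReference:
    """In-memory reference accessor backed by {chrom: sequence} (for tests)."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = seqs

    def get_base(self, chrom: str, pos1: int) -> str:
        seq = self.seqs.get(chrom, "")
        return seq[pos1 - 1] if 0 <= pos1 - 1 < len(seq) else "N"

    def get_seq(self, chrom: str, start0: int, end0: int) -> str:
        return "".join(self.get_base(chrom, p + 1) for p in range(start0, end0))


@dataclass
class TruthSet:
    """Ground-truth genotypes for the tetrad over both DNA sources.

    ``variants`` has one row per variant site with columns ``chrom``,
    ``pos`` (1-based), ``ref``, ``alt``, ``origin`` ("population" or
    "lcl_de_novo"), ``population_af``, ``known_flag``, and an alt-allele
    dose column ``gt_<sample>_<source>`` (0/1/2) for each of the eight
    sample-source combinations.
    """

    pedigree: Pedigree
    targets: list[TargetRegion]
    reference: SyntheticReference
    variants: pd.DataFrame

    def gt_column(self, sample: str, source: str) -> str:
        return f"gt_{sample}_{source}"

    def keys_for(self, sample: str, source: str) -> set[tuple]:
        v = self.variants
        mask = v[self.gt_column(sample, source)] > 0
        return set(zip(v.loc[mask, "chrom"], v.loc[mask, "pos"],
                       v.loc[mask, "ref"], v.loc[mask, "alt"]))

    def known_site_keys(self) -> set[tuple]:
        v = self.variants
        mask = v["known_flag"]
        return set(zip(v.loc[mask, "chrom"], v.loc[mask, "pos"],
                       v.loc[mask, "ref"], v.loc[mask, "alt"]))

    def de_novo_keys(self, sample: Optional[str] = None) -> set[tuple]:
        v = self.variants[self.variants["origin"] == "lcl_de_novo"]
        if sample is not None:
            v = v[v[self.gt_column(sample, "LCL")] > 0]
        return set(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))


def generate_targets(config: SimulationConfig) -> list[TargetRegion]:
    """Place non-overlapping, sorted capture regions uniformly in the genome."""
    n, L, G = config.n_target_regions, config.target_region_length, config.genome_length
    if n == 0:
        return []
    if G < n * L:
        raise ValueError("target regions cannot fit in the genome without overlap")
    rng = _stage_rng(config.seed, _TAG_TARGETS)
    # Stars-and-bars: sorted draws in the free space, shifted by region lengths.
    slack = np.sort(rng.integers(0, G - n * L + 1, size=n))
    starts = slack + np.arange(n, dtype=np.int64) * L
    return [TargetRegion(config.chrom, int(s), int(s) + L) for s in starts]


def _targeted_flat_to_pos(targets: Sequence[TargetRegion], flat: np.ndarray) -> np.ndarray:
    """Map flat indices over the concatenated targeted bp to 1-based positions."""
    lengths = np.array([len(t) for t in targets], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    region = np.searchsorted(cum, flat, side="right") - 1
    starts = np.array([t.start for t in targets], dtype=np.int64)
    return starts[region] + (flat - cum[region]) + 1


def _draw_alt_alleles(rng: np.random.Generator, ref_idx: np.ndarray,
                      spectrum_weights: Sequence[float]) -> np.ndarray:
    """Draw alt base indices conditional on ref base from the 12-class spectrum."""
    w = np.asarray(spectrum_weights, dtype=float).reshape(4, 3)
    probs = np.zeros((4, 4))
    for r in range(4):
        probs[r, _OTHERS[r]] = w[r] / w[r].sum()
    cum = np.cumsum(probs, axis=1)[ref_idx]  # (n, 4)
    u = rng.random(len(ref_idx))
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


def generate_pedigree_truth(targets: Sequence[TargetRegion],
                            config: SimulationConfig,
                            pedigree: Optional[Pedigree] = None,
                            reference: Optional[SyntheticReference] = None) -> TruthSet:
    """Draw segregating family variants under Hardy-Weinberg and Mendelian transmission.

    Founder genotypes are sampled per site from the configured allele-frequency
    distribution; each child receives one uniformly chosen allele from each
    parent.  Sites at which no family member carries the alternate allele are
    dropped.  PBMC and LCL genotypes are identical at this stage.
    """
    pedigree = pedigree or Pedigree.tetrad()
    targets = list(targets)
    reference = reference or SyntheticReference(targets, config.seed)
    rng = _stage_rng(config.seed, _TAG_TRUTH)

    T = sum(len(t) for t in targets)
    if config.variant_density > 0 and T == 0:
        raise ValueError("variant_density > 0 requires non-empty targets")

    columns = ["chrom", "pos", "ref", "alt", "origin", "population_af", "known_flag"]
    gt_cols = [f"gt_{s}_{src}" for s in pedigree.sample_ids for src in SOURCES]
    empty = pd.DataFrame({c: pd.Series(dtype=object) for c in columns + gt_cols})
    if config.variant_density == 0 or T == 0:
        return TruthSet(pedigree, targets, reference, empty)

    carrier = config.mean_carrier_probability()
    lam = config.variant_density * T / carrier
    n_sites = int(rng.poisson(lam))
    if n_sites == 0:
        return TruthSet(pedigree, targets, reference, empty)

    flat = np.unique(rng.integers(0, T, size=n_sites))
    pos = _targeted_flat_to_pos(targets, flat)
    n = len(pos)

    ref_bases = np.array([reference.get_base(config.chrom, int(p)) for p in pos])
    ref_idx = np.array([_BASE_IDX[b] for b in ref_bases])
    alt_idx = _draw_alt_alleles(rng, ref_idx, config.spectrum_weights)
    alt_bases = np.array(list(BASES))[alt_idx]

    af = config.sample_af(rng, n)
    # Founder alleles, then transmission of one allele per parent per child.
    fa = rng.random((n, 2)) < af[:, None]
    mo = rng.random((n, 2)) < af[:, None]
    picks = rng.integers(0, 2, size=(n, 4))  # father->c1, mother->c1, father->c2, mother->c2
    c1 = fa[np.arange(n), picks[:, 0]].astype(int) + mo[np.arange(n), picks[:, 1]].astype(int)
    c2 = fa[np.arange(n), picks[:, 2]].astype(int) + mo[np.arange(n), picks[:, 3]].astype(int)
    gts = {
        pedigree.father: fa.sum(axis=1),
        pedigree.mother: mo.sum(axis=1),
        pedigree.children[0]: c1,
        pedigree.children[1]: c2,
    }

    keep = sum(gts.values()) > 0
    known = rng.random(n) >= config.novel_fraction

    data = {
        "chrom": np.full(n, config.chrom, dtype=object),
        "pos": pos.astype(np.int64),
        "ref": ref_bases.astype(object),
        "alt": alt_bases.astype(object),
        "origin": np.full(n, "population", dtype=object),
        "population_af": af,
        "known_flag": known,
    }
    for s in pedigree.sample_ids:
        for src in SOURCES:
            data[f"gt_{s}_{src}"] = gts[s].astype(np.int8)
    df = pd.DataFrame(data)[keep].reset_index(drop=True)
    return TruthSet(pedigree, targets, reference, df)


def apply_lcl_mutations(truth: TruthSet, config: SimulationConfig) -> TruthSet:
    """Plant heterozygous LCL-only de novo mutations into each individual's LCL.

    The planted count per LCL is Binomial(n, de_novo_rate) where n is that
    individual's PBMC call (carrier-site) count; positions are drawn from
    targeted bp not already variant in the family; the substitution type
    follows the configured spectrum; planted variants are absent from the
    known-sites surrogate.
    """
    rng = _stage_rng(config.seed, _TAG_DENOVO)
    pedigree, targets = truth.pedigree, truth.targets
    T = sum(len(t) for t in targets)
    used = set(truth.variants["pos"].tolist())

    rows = []
    for sample in pedigree.sample_ids:
        n_carrier = int((truth.variants[truth.gt_column(sample, "PBMC")] > 0).sum())
        n_plant = int(rng.binomial(n_carrier, config.de_novo_rate)) if n_carrier else 0
        if n_plant == 0:
            continue
        if T - len(used) < n_plant:
            raise ValueError("de_novo_rate too high: candidate positions exhausted")
        chosen: list[int] = []
        while len(chosen) < n_plant:
            flat = rng.integers(0, T, size=4 * n_plant)
            for p in _targeted_flat_to_pos(targets, flat):
                p = int(p)
                if p not in used:
                    used.add(p)
                    chosen.append(p)
                    if len(chosen) == n_plant:
                        break
        for p in sorted(chosen):
            ref = truth.reference.get_base(config.chrom, p)
            alt_i = int(_draw_alt_alleles(rng, np.array([_BASE_IDX[ref]]),
                                          config.spectrum_weights)[0])
            row = {
                "chrom": config.chrom, "pos": p, "ref": ref, "alt": BASES[alt_i],
                "origin": "lcl_de_novo", "population_af": 0.0, "known_flag": False,
            }
            for s in pedigree.sample_ids:
                for src in SOURCES:
                    row[f"gt_{s}_{src}"] = np.int8(1 if (s == sample and src == "LCL") else 0)
            rows.append(row)

    if not rows:
        return TruthSet(pedigree, targets, truth.reference, truth.variants.copy())
    merged = pd.concat([truth.variants, pd.DataFrame(rows)], ignore_index=True)
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return TruthSet(pedigree, targets, truth.reference, merged)


def _two_point_mean(rng: np.random.Generator, counts: np.ndarray,
                    high: float, low: float, low_fraction: float) -> np.ndarray:
    out = np.zeros(counts.shape, dtype=float)
    nz = counts > 0
    if low_fraction == 0.0:
        out[nz] = high
        return out
    n_low = rng.binomial(counts[nz], low_fraction)
    out[nz] = high - (high - low) * n_low / counts[nz]
    return out


def simulate_pileups(truth: TruthSet, config: SimulationConfig) -> pd.DataFrame:
    """Draw per-site read pileups for all eight sample-source combinations.

    Depth is Poisson(mean_depth); each read's allele is drawn from the
    genotype (het -> 1/2 each) then miscalled with probability
    ``base_error_rate`` to a uniformly chosen other base; strand is
    Bernoulli(strand_bias); base and mapping qualities follow the two-point
    model.  Non-variant targeted sites are emitted at
    ``invariant_site_density`` so false positives are measurable.
    Zero-depth sites are omitted.
    """
    rng = _stage_rng(config.seed, _TAG_PILEUPS)
    pedigree, targets = truth.pedigree, truth.targets
    T = sum(len(t) for t in targets)

    # Site list: truth sites plus sparse non-variant sites.
    v = truth.variants
    var_pos = v["pos"].to_numpy(dtype=np.int64) if len(v) else np.empty(0, dtype=np.int64)
    used = set(var_pos.tolist())
    if config.invariant_site_density >= 1.0:
        all_pos = _targeted_flat_to_pos(targets, np.arange(T)) if T else np.empty(0, np.int64)
        inv_pos = np.array(sorted(set(all_pos.tolist()) - used), dtype=np.int64)
    elif config.invariant_site_density > 0 and T > 0:
        n_inv = rng.poisson(config.invariant_site_density * T)
        flat = np.unique(rng.integers(0, T, size=n_inv)) if n_inv else np.empty(0, np.int64)
        cand = _targeted_flat_to_pos(targets, flat)
        inv_pos = np.array([p for p in cand if int(p) not in used], dtype=np.int64)
    else:
        inv_pos = np.empty(0, dtype=np.int64)

    pos = np.concatenate([var_pos, inv_pos])
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    n = len(pos)
    if n == 0 or config.mean_depth == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in PILEUP_COLUMNS})

    ref_bases = np.concatenate([
        v["ref"].to_numpy(dtype=object) if len(v) else np.empty(0, object),
        np.array([truth.reference.get_base(config.chrom, int(p)) for p in inv_pos], dtype=object),
    ])[order]
    alt_bases = np.concatenate([
        v["alt"].to_numpy(dtype=object) if len(v) else np.empty(0, object),
        np.full(len(inv_pos), None, dtype=object),
    ])[order]
    ref_idx = np.array([_BASE_IDX[b] for b in ref_bases])
    alt_idx = np.array([_BASE_IDX[b] if b is not None else _BASE_IDX[r]
                        for b, r in zip(alt_bases, ref_bases)])

    gt_dose = {}
    for s in pedigree.sample_ids:
        for src in SOURCES:
            col = v[truth.gt_column(s, src)].to_numpy() if len(v) else np.empty(0, np.int8)
            gt_dose[(s, src)] = np.concatenate([col, np.zeros(len(inv_pos), np.int8)])[order]

    eps = config.base_error_rate
    frames = []
    for s in pedigree.sample_ids:
        for src in SOURCES:
            g = gt_dose[(s, src)].astype(float)
            depth = rng.poisson(config.mean_depth, size=n)
            n_alt = rng.binomial(depth, g / 2.0)
            n_ref = depth - n_alt
            base_counts = np.zeros((n, 4), dtype=np.int64)
            rows_i = np.arange(n)
            for origin_counts, origin_idx in ((n_ref, ref_idx), (n_alt, alt_idx)):
                err = rng.binomial(origin_counts, eps) if eps > 0 else np.zeros(n, np.int64)
                np.add.at(base_counts, (rows_i, origin_idx), origin_counts - err)
                if eps > 0:
                    c1 = rng.binomial(err, 1.0 / 3.0)
                    c2 = rng.binomial(err - c1, 0.5)
                    c3 = err - c1 - c2
                    others = _OTHERS[origin_idx]  # (n, 3)
                    for j, cj in enumerate((c1, c2, c3)):
                        np.add.at(base_counts, (rows_i, others[:, j]), cj)
            fwd = rng.binomial(base_counts, config.strand_bias)
            rev = base_counts - fwd
            bq = _two_point_mean(rng, base_counts, config.base_quality_high,
                                 config.base_quality_low, config.low_base_quality_fraction)
            mq = _two_point_mean(rng, depth, config.mapping_quality_high,
                                 config.mapping_quality_low, config.low_mapping_quality_fraction)
            keep = depth > 0
            frame = {
                "chrom": np.full(n, config.chrom, dtype=object)[keep],
                "pos": pos[keep],
                "sample": np.full(n, s, dtype=object)[keep],
                "source": np.full(n, src, dtype=object)[keep],
                "ref": ref_bases[keep],
            }
            for j, b in enumerate(BASES):
                frame[f"{b}_fwd"] = fwd[keep, j]
            for j, b in enumerate(BASES):
                frame[f"{b}_rev"] = rev[keep, j]
            for j, b in enumerate(BASES):
                frame[f"{b}_bq"] = bq[keep, j]
            frame["mq"] = mq[keep]
            frames.append(pd.DataFrame(frame))

    out = pd.concat(frames, ignore_index=True)
    return out[list(PILEUP_COLUMNS)]


@dataclass
class TetradSimulation:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    pedigree: Pedigree
    targets: list[TargetRegion]
    reference: SyntheticReference
    truth: TruthSet
    pileups: pd.DataFrame


def simulate_tetrad(config: SimulationConfig,
                    pedigree: Optional[Pedigree] = None) -> TetradSimulation:
    """Run the full generator: targets -> truth -> LCL mutations -> pileups."""
    pedigree = pedigree or Pedigree.tetrad()
    targets = generate_targets(config)
    truth = generate_pedigree_truth(targets, config, pedigree=pedigree)
    truth = apply_lcl_mutations(truth, config)
    pileups = simulate_pileups(truth, config)
    return TetradSimulation(config, pedigree, targets, truth.reference, truth, pileups)
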