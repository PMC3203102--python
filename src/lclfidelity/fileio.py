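"""Readers and writers for the pipeline's on-disk formats.

VCF 4.2 (uncompressed, via pysam) for calls, truth and known sites; BED
(0-based half-open) for capture targets; PED for the pedigree; a documented
TSV dialect for pileups (one row per sample-source-site with per-base
forward/reverse counts, per-base mean base quality and site mean mapping
quality).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .config import BASES
from .genotyper import CALL_COLUMNS, CallSet
from .simulate import PILEUP_COLUMNS, Pedigree, PedigreeMember, TargetRegion, TruthSet

_GT_CODE = {"het": (0, 1), "hom-alt": (1, 1), "hom-ref": (0, 0)}
_CODE_GT = {v: k for k, v in _GT_CODE.items()}


def write_bed(targets: Sequence[TargetRegion], path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


def read_bed(path) -> list[TargetRegion]:
    targets = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            targets.append(TargetRegion(chrom, int(start), int(end)))
    return targets


def write_ped(pedigree: Pedigree, path, family_id: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for m in pedigree.members:
            fh.write("\t".join([family_id, m.sample_id, m.father_id or "0",
                                m.mother_id or "0", m.sex, "0"]) + "\n")


def read_ped(path) -> Pedigree:
    members = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, sid, fid, mid, sex = line.split()[:5]
            members.append(PedigreeMember(sid, None if fid == "0" else fid,
                                          None if mid == "0" else mid, sex))
    return Pedigree(tuple(members))


def write_pileups_tsv(pileups: pd.DataFrame, path) -> None:
    pileups.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pileups_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    return df[list(PILEUP_COLUMNS)]


def _make_header(contigs: Mapping[str, int], samples: Sequence[str],
                 filters: Iterable[str] = ("high", "rescue")) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for f in filters:
        if f not in ("PASS",):
            header.filters.add(f, None, None, f"{f} stringency tier")
    header.info.add("AFRAC", 1, "Float", "Alternate allele fraction of site depth")
    header.info.add("ADF", 1, "Integer", "Alternate-supporting reads, forward strand")
    header.info.add("ADR", 1, "Integer", "Alternate-supporting reads, reverse strand")
    header.info.add("GP", 1, "Float", "Posterior probability of the called genotype")
    header.info.add("ORIGIN", 1, "String", "Truth origin (population or lcl_de_novo)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    return header


def write_calls_vcf(callset: CallSet, path, contigs: Mapping[str, int]) -> None:
    """Write one sample-source call set as VCF 4.2; FILTER names the tier."""
    name = f"{callset.sample_id}.{callset.source}"
    header = _make_header(contigs, [name], filters=[callset.tier])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in callset.calls.sort_values(["chrom", "pos"], kind="mergesort").iterrows():
            rec = vcf.new_record(
                contig=row["chrom"], start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]), filter=callset.tier)
            rec.info["AFRAC"] = float(row["alt_fraction"])
            rec.info["ADF"] = int(row["alt_forward"])
            rec.info["ADR"] = int(row["alt_reverse"])
            rec.info["GP"] = float(row["genotype_posterior"])
            rec.samples[name]["GT"] = _GT_CODE[row["genotype"]]
            rec.samples[name]["DP"] = int(row["depth"])
            alt_reads = int(row["alt_forward"]) + int(row["alt_reverse"])
            rec.samples[name]["AD"] = (int(row["depth"]) - alt_reads, alt_reads)
            vcf.write(rec)


def read_calls_vcf(path) -> CallSet:
    """Read a call-set VCF written by :func:`write_calls_vcf`."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        names = list(vcf.header.samples)
        if len(names) != 1:
            raise ValueError("expected a single-sample call VCF")
        name = names[0]
        sample_id, _, source = name.rpartition(".")
        tier = None
        for rec in vcf:
            tier = next(iter(rec.filter.keys()), "PASS")
            fmt = rec.samples[name]
            gt = _CODE_GT.get(tuple(fmt["GT"]), "het")
            alt = rec.alts[0]
            rows.append({
                "chrom": rec.contig, "pos": rec.pos, "ref": rec.ref, "alt": alt,
                "genotype": gt, "depth": int(fmt["DP"]),
                "alt_fraction": float(rec.info["AFRAC"]),
                "alt_forward": int(rec.info["ADF"]),
                "alt_reverse": int(rec.info["ADR"]),
                "genotype_posterior": float(rec.info["GP"]),
                "tier": tier,
                "variant_class": ("snv" if len(rec.ref) == len(alt) == 1 else
                                  "insertion" if len(alt) > len(rec.ref) else "deletion"),
            })
    calls = pd.DataFrame(rows, columns=list(CALL_COLUMNS)) if rows else \
        pd.DataFrame({c: pd.Series(dtype=object) for c in CALL_COLUMNS})
    return CallSet(sample_id, source, tier or "PASS", calls)


def write_known_sites_vcf(keys: Iterable[tuple], path,
                          contigs: Mapping[str, int]) -> None:
    """Sites-only VCF surrogate for the known-variant databases."""
    header = _make_header(contigs, [], filters=[])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, ref, alt in sorted(set(keys)):
            rec = vcf.new_record(contig=chrom, start=int(pos) - 1,
                                 alleles=(ref, alt))
            rec.filter.add("PASS")
            vcf.write(rec)


def read_known_sites_vcf(path) -> set:
    keys = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                keys.add((rec.contig, rec.pos, rec.ref, alt))
    return keys


def write_truth_vcfs(truth: TruthSet, outdir, contigs: Mapping[str, int]) -> None:
    """Per sample-source truth VCFs plus a merged 8-column multi-sample VCF."""
    os.makedirs(outdir, exist_ok=True)
    v = truth.variants
    names = [f"{s}.{src}" for s in truth.pedigree.sample_ids for src in ("PBMC", "LCL")]
    header = _make_header(contigs, names, filters=[])
    with pysam.VariantFile(os.path.join(outdir, "truth.merged.vcf"), "w",
                           header=header) as vcf:
        for _, row in v.iterrows():
            rec = vcf.new_record(contig=row["chrom"], start=int(row["pos"]) - 1,
                                 alleles=(row["ref"], row["alt"]))
            rec.filter.add("PASS")
            rec.info["ORIGIN"] = row["origin"]
            for s in truth.pedigree.sample_ids:
                for src in ("PBMC", "LCL"):
                    dose = int(row[truth.gt_column(s, src)])
                    rec.samples[f"{s}.{src}"]["GT"] = ((0, 0), (0, 1), (1, 1))[dose]
            vcf.write(rec)
    for s in truth.pedigree.sample_ids:
        for src in ("PBMC", "LCL"):
            name = f"{s}.{src}"
            h = _make_header(contigs, [name], filters=[])
            sub = v[v[truth.gt_column(s, src)] > 0]
            with pysam.VariantFile(os.path.join(outdir, f"truth.{s}.{src}.vcf"),
                                   "w", header=h) as vcf:
                for _, row in sub.iterrows():
                    rec = vcf.new_record(contig=row["chrom"], start=int(row["pos"]) - 1,
                                         alleles=(row["ref"], row["alt"]))
                    rec.filter.add("PASS")
                    rec.info["ORIGIN"] = row["origin"]
                    dose = int(row[truth.gt_column(s, src)])
                    rec.samples[name]["GT"] = ((0, 0), (0, 1), (1, 1))[dose]
                    vcf.write(rec)
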