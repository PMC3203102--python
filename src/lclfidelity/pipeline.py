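"""End-to-end orchestration: simulate -> call -> compare -> rescue -> classify
-> annotate -> report.

A single master seed (the simulation seed) drives every stage; re-running
with an identical configuration reproduces the report bit-for-bit.  The
report is the analysis summary a paired-source exome study prints: per
sample-source call totals and novel/coding fractions, per-individual
pre/post-rescue concordance and Venn counts, the pooled discordance
accounting (shared-or-known vs de novo candidates), the substitution
spectrum of the candidates, Mendelian-violation counts, coverage
summaries, and the implied de novo rate (100 minus the mean post-rescue
concordance).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

from .annotation import annotate_snv, toy_gene_model
from .concordance import compare_pair, rescue_discordant, venn_counts
from .config import PipelineConfig
from .denovo import (classify_discordant, mendelian_check, select_validation_candidates,
                     substitution_spectrum)
from .genotyper import call_sample, coverage_summary
from .simulate import SOURCES, simulate_tetrad

CODING_EFFECTS = frozenset({"synonymous", "non-synonymous", "nonsense",
                            "frameshift", "inframe_indel", "utr5", "utr3"})


def implied_de_novo_rate(final_average_concordance_pct: float) -> float:
    """De novo rate (%) implied by a final average concordance rate (%).

    The residual post-rescue discordance — variants genuinely private to one
    DNA source — is 100 minus the final concordance percentage.
    """
    return round(100.0 - final_average_concordance_pct, 6)


def _r(x: Optional[float], nd: int = 6) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return round(float(x), nd)


@dataclass
class RunReport:
    """Serializable summary of one pipeline run."""

    config: dict
    per_sample_source: dict
    per_individual: dict
    pooled: dict
    spectrum: dict
    de_novo: dict
    validation_candidates: list
    coverage: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)

    def to_text(self) -> str:
        lines = ["Paired-source variant fidelity report", "=" * 38]
        for name, d in sorted(self.per_sample_source.items()):
            lines.append(
                f"{name}: {d['n_calls']} calls "
                f"({d['n_snv']} SNV / {d['n_indel']} indel), "
                f"novel {d['novel_fraction_pct']}%, coding {d['coding_fraction_pct']}%")
        lines.append("")
        for sid, d in sorted(self.per_individual.items()):
            pre, post = d["pre_rescue"], d["post_rescue"]
            lines.append(
                f"{sid}: concordance {pre['rate_pct']}% -> {post['rate_pct']}% "
                f"(venn pre {pre['venn']}, post {post['venn']})")
        p = self.pooled
        lines += [
            "",
            f"mean concordance: {p['mean_pre_rescue_rate_pct']}% pre-rescue, "
            f"{p['mean_post_rescue_rate_pct']}% post-rescue",
            f"pooled discordant (post-rescue): {p['discordant_total_pooled']} "
            f"({p['shared_or_known']} shared/known, "
            f"{p['de_novo_candidate']} de novo candidates)",
            f"implied de novo rate: {p['implied_de_novo_rate_pct']}%",
        ]
        return "\n".join(lines)


def run_pipeline(config: Optional[PipelineConfig] = None,
                 outdir: Optional[str] = None) -> RunReport:
    """Execute every stage on a fresh simulation and build the report.

    With ``outdir`` (or ``config.outdir``) set, all intermediate artifacts
    are written there: targets BED, pedigree PED, pileup TSV, truth and
    call VCFs, known-sites VCF, comparison TSV and the report (JSON and
    text).
    """
    config = config or PipelineConfig()
    for w in config.validate():
        import warnings
        warnings.warn(w, stacklevel=2)
    outdir = outdir or config.outdir

    sim = simulate_tetrad(config.simulation)
    pedigree, truth, pileups = sim.pedigree, sim.truth, sim.pileups
    known_sites = truth.known_site_keys()

    callsets = {}
    for s in pedigree.sample_ids:
        for src in SOURCES:
            sub = pileups[(pileups["sample"] == s) & (pileups["source"] == src)]
            callsets[(s, src)] = call_sample(sub.reset_index(drop=True),
                                             config.high_profile, config.model,
                                             sample_id=s, source=src)

    def _rate(pair, snv_only=False):
        if not snv_only:
            return pair.concordance_rate
        def is_snv(k):
            return len(k[2]) == 1 and len(k[3]) == 1
        c = sum(1 for k in pair.concordant if is_snv(k))
        u = c + sum(1 for k in (pair.discordant_pbmc_only | pair.discordant_lcl_only
                                | pair.genotype_mismatch) if is_snv(k))
        return 100.0 * c / u if u else math.nan

    per_individual, pairs_post, rescue_records = {}, {}, {}
    for s in pedigree.sample_ids:
        pre = compare_pair(callsets[(s, "PBMC")], callsets[(s, "LCL")],
                           genotype_aware=config.genotype_aware_concordance)
        post, records = rescue_discordant(pre, pileups, config.rescue_profile,
                                          config.high_profile, config.model)
        pairs_post[s] = post
        rescue_records[s] = records
        reasons: dict[str, int] = {}
        for r in records:
            reasons[r.rescue_reason] = reasons.get(r.rescue_reason, 0) + 1
        per_individual[s] = {
            "pre_rescue": {"venn": list(venn_counts(pre)),
                           "rate_pct": _r(_rate(pre)),
                           "rate_snv_pct": _r(_rate(pre, snv_only=True))},
            "post_rescue": {"venn": list(venn_counts(post)),
                            "rate_pct": _r(_rate(post)),
                            "rate_snv_pct": _r(_rate(post, snv_only=True))},
            "rescue_reasons": reasons,
        }

    remaining_pooled = set()
    per_pair_total = 0
    for s, post in pairs_post.items():
        disc = post.discordant_pbmc_only | post.discordant_lcl_only
        remaining_pooled |= disc
        per_pair_total += len(disc)

    all_callsets = [callsets[(s, src)] for s in pedigree.sample_ids for src in SOURCES]
    classifications = (classify_discordant(remaining_pooled, all_callsets, known_sites)
                       if remaining_pooled else [])
    candidates = [c for c in classifications if c.category == "de_novo_candidate"]
    shared = [c for c in classifications if c.category == "shared_or_known"]

    # Mendelian checks on both sources' call sets of each child.
    mendelian = {}
    for child in pedigree.children:
        for src in SOURCES:
            v = mendelian_check(callsets[(child, src)],
                                callsets[(pedigree.father, src)],
                                callsets[(pedigree.mother, src)])
            mendelian[f"{child}.{src}"] = len(v)

    snv_candidates = [c.key for c in candidates if len(c.key[2]) == len(c.key[3]) == 1]
    spectrum = substitution_spectrum(snv_candidates)

    gene_model = toy_gene_model(sim.targets, splice_window=config.splice_window,
                                near_gene_bp=config.near_gene_bp)
    annotations = {c.key: annotate_snv(c.key, gene_model, sim.reference).effect
                   for c in candidates}
    validation = select_validation_candidates(candidates, annotations)

    per_sample_source = {}
    coverage = {}
    for s in pedigree.sample_ids:
        for src in SOURCES:
            cs = callsets[(s, src)]
            keys = cs.keys()
            n = len(cs)
            novel = sum(1 for k in keys if k not in known_sites)
            coding = None
            if config.annotate_all_calls and n:
                effects = (annotate_snv(k, gene_model, sim.reference).effect
                           for k in keys)
                coding = 100.0 * sum(1 for e in effects if e in CODING_EFFECTS) / n
            n_snv = int(sum(1 for k in keys if len(k[2]) == len(k[3]) == 1))
            per_sample_source[f"{s}.{src}"] = {
                "n_calls": n, "n_snv": n_snv, "n_indel": n - n_snv,
                "novel_fraction_pct": _r(100.0 * novel / n) if n else None,
                "coding_fraction_pct": _r(coding),
            }
            sub = pileups[(pileups["sample"] == s) & (pileups["source"] == src)]
            if sim.targets and len(sub):
                cov = coverage_summary(sub, sim.targets, depth_threshold=8)
                count_cols = [c for c in sub.columns if c.endswith(("_fwd", "_rev"))]
                emitted_mean = float(sub[count_cols].to_numpy().sum(axis=1).mean())
                coverage[f"{s}.{src}"] = {
                    "targeted_mean_depth": _r(cov.mean_depth),
                    "fraction_ge_8x": _r(cov.fraction_at_or_above_threshold),
                    "emitted_site_mean_depth": _r(emitted_mean),
                }

    rates_post = [pairs_post[s].concordance_rate for s in pedigree.sample_ids]
    rates_pre = [per_individual[s]["pre_rescue"]["rate_pct"] for s in pedigree.sample_ids]
    defined_post = [r for r in rates_post if not math.isnan(r)]
    defined_pre = [r for r in rates_pre if r is not None]
    mean_post = sum(defined_post) / len(defined_post) if defined_post else None
    mean_pre = sum(defined_pre) / len(defined_pre) if defined_pre else None

    planted = truth.de_novo_keys()
    recovered_true = planted & {c.key for c in candidates}
    pooled = {
        "discordant_total_pooled": len(remaining_pooled),
        "discordant_total_per_pair_sum": per_pair_total,
        "shared_or_known": len(shared),
        "de_novo_candidate": len(candidates),
        "mean_pre_rescue_rate_pct": _r(mean_pre),
        "mean_post_rescue_rate_pct": _r(mean_post),
        "implied_de_novo_rate_pct": (implied_de_novo_rate(mean_post)
                                     if mean_post is not None else None),
        "mendelian_violations": mendelian,
    }
    de_novo = {
        "planted": len(planted),
        "candidates": sorted({c.key for c in candidates}),
        "recovered_true": len(recovered_true),
        "false_candidates": len(candidates) - len(recovered_true),
        "sensitivity_pct": _r(100.0 * len(recovered_true) / len(planted))
        if planted else None,
        # Pooled candidates over pooled LCL calls: the per-sample fraction of
        # an LCL's calls that are culture-acquired.
        "candidate_rate_pct": _r(
            100.0 * len(candidates)
            / max(1, sum(len(callsets[(s, "LCL")]) for s in pedigree.sample_ids))),
    }

    report = RunReport(
        config=dataclasses.asdict(config),
        per_sample_source=per_sample_source,
        per_individual=per_individual,
        pooled=pooled,
        spectrum=dict(spectrum.counts),
        de_novo=de_novo,
        validation_candidates=[list(k) for k in validation],
        coverage=coverage,
    )

    if outdir:
        _write_artifacts(outdir, config, sim, callsets, pairs_post,
                         rescue_records, classifications, report)
    return report


def _write_artifacts(outdir, config, sim, callsets, pairs_post,
                     rescue_records, classifications, report) -> None:
    from . import fileio

    os.makedirs(outdir, exist_ok=True)
    contigs = {config.simulation.chrom: config.simulation.genome_length}
    fileio.write_bed(sim.targets, os.path.join(outdir, "targets.bed"))
    fileio.write_ped(sim.pedigree, os.path.join(outdir, "pedigree.ped"))
    fileio.write_pileups_tsv(sim.pileups, os.path.join(outdir, "pileups.tsv"))
    fileio.write_truth_vcfs(sim.truth, os.path.join(outdir, "truth"), contigs)
    fileio.write_known_sites_vcf(sim.truth.known_site_keys(),
                                 os.path.join(outdir, "known_sites.vcf"), contigs)
    for (s, src), cs in callsets.items():
        fileio.write_calls_vcf(cs, os.path.join(outdir, f"calls.{s}.{src}.vcf"), contigs)
    with open(os.path.join(outdir, "comparison.tsv"), "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\tstatus\tstage\trescue_reason\n")
        for s, post in sorted(pairs_post.items()):
            rescued = {r.key: r for r in rescue_records[s]}
            for key in sorted(post.concordant | post.discordant_pbmc_only
                              | post.discordant_lcl_only):
                if key in post.concordant:
                    status = "concordant"
                elif key in post.discordant_pbmc_only:
                    status = "pbmc_only"
                else:
                    status = "lcl_only"
                reason = rescued[key].rescue_reason if key in rescued else "."
                fh.write(f"{s}\t{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t"
                         f"{status}\tpost_rescue\t{reason}\n")
    with open(os.path.join(outdir, "classifications.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcategory\tknown\tcarriers\n")
        for c in classifications:
            carriers = ";".join(f"{s}:{src}" for s, src in c.carriers)
            fh.write(f"{c.key[0]}\t{c.key[1]}\t{c.key[2]}\t{c.key[3]}\t"
                     f"{c.category}\t{int(c.known_flag)}\t{carriers}\n")
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json() + "\n")
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write(report.to_text() + "\n")
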