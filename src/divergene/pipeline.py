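"""End-to-end orchestration: synthetic inputs -> DE -> enrichment ->
homology -> SSR mining -> SNP filtering -> diversity, driven by one
config file.

Every threshold lives in the :class:`RunConfig` and is echoed to the run
log; each stage reads and writes plain files under the output directory,
so any single stage can be re-run from its on-disk inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import enrichment, expression, homology, popdiv, snpmine, ssrmine, synthio

__all__ = ["RunConfig", "assembly_summary", "run"]

log = logging.getLogger("divergene")

STAGES = ["synth", "expression", "enrichment", "homology", "ssr", "snp", "diversity"]
# stages whose inputs come from an earlier stage's outputs
_DEPENDS = {
    "expression": ["synth"],
    "enrichment": ["expression"],
    "homology": ["synth"],
    "ssr": ["synth", "homology"],
    "snp": ["synth"],
    "diversity": ["synth"],
}


@dataclass
class RunConfig:
    outdir: str = "divergene_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    synth: dict = field(default_factory=dict)
    evalue_cutoff: float = 1e-10
    reciprocal_orthologs: bool = False
    de_fdr: float = 1e-2
    de_fc: float = 2.0
    ssr_thresholds: dict[int, int] = field(default_factory=lambda: dict(ssrmine.DEFAULT_THRESHOLDS))
    ssr_min_seq_len: int = 1000
    snp_min_depth: int = 10
    snp_min_score: float = 30.0
    snp_min_spacing: int = 5
    bootstrap_B: int = 200
    aligner: str = "blastn"  # or "sw" for desk-scale exact alignment

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in doc.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "stages":
                unknown = set(value) - set(STAGES)
                if unknown:
                    raise ValueError(f"unknown stages: {sorted(unknown)}")
                cfg.stages.update(value)
            elif key == "ssr_thresholds":
                cfg.ssr_thresholds = {int(k): int(v) for k, v in value.items()}
            else:
                setattr(cfg, key, value)
        return cfg

    def synth_spec(self) -> synthio.SynthSpec:
        params = dict(self.synth)
        params.setdefault("seed", self.seed)
        if "allele_freqs" in params and params["allele_freqs"] is not None:
            params["allele_freqs"] = tuple(tuple(v) for v in params["allele_freqs"])
        return synthio.SynthSpec(**params)


def assembly_summary(lengths: Sequence[int]) -> dict:
    """Count, mean length and N50 of an assembly.

    N50 is the length of the sequence at which the cumulative sum of
    descending-sorted lengths first reaches half the total.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("assembly summary requires at least one sequence")
    if min(lengths) <= 0:
        raise ValueError("sequence lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    n50 = ordered[-1]
    for L in ordered:
        acc += L
        if acc >= half:
            n50 = L
            break
    return {"count": len(lengths), "mean_length": sum(lengths) / len(lengths), "n50": n50}


def _stage_guard(config: RunConfig, stage: str, done: set[str]) -> bool:
    if not config.stages.get(stage, True):
        log.warning("stage %s disabled; skipping", stage)
        return False
    missing = [d for d in _DEPENDS.get(stage, []) if d not in done]
    if missing:
        log.warning("stage %s depends on disabled stage(s) %s; skipping", stage, missing)
        return False
    return True


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the machine-readable summary.

    Per-stage outputs land under ``config.outdir``; a summary JSON, the
    effective configuration and a log file are always written.  A stage
    failure aborts with the stage name; outputs of completed stages are
    retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("configuration: %s", json.dumps(asdict(config), default=str, sort_keys=True))

    summary: dict = {"seed": config.seed, "stages_run": []}
    done: set[str] = set()
    stage = "synth"
    try:
        # ---------------- synth ----------------
        spec = config.synth_spec()
        if _stage_guard(config, "synth", done):
            synthdir = outdir / "synth"
            synthio.write_all(spec, synthdir)
            p_set = synthio.UnigeneSet.read_fasta(synthdir / "unigenes_P.fasta", "P")
            g_set = synthio.UnigeneSet.read_fasta(synthdir / "unigenes_G.fasta", "G")
            summary["assembly"] = {
                "P": assembly_summary(p_set.lengths()),
                "G": assembly_summary(g_set.lengths()),
            }
            done.add(stage)
            summary["stages_run"].append(stage)

        # ---------------- expression ----------------
        stage = "expression"
        degs: list[str] = []
        if _stage_guard(config, stage, done):
            counts = expression.read_counts(outdir / "synth" / "counts.tsv")
            results = expression.call_degs(
                counts, fdr_threshold=config.de_fdr, fc_threshold=config.de_fc
            )
            expression.write_de_table(results, outdir / "de_table.tsv")
            degs = [r.gene_id for r in results if r.is_deg]
            up = sum(r.direction == "up" for r in results if r.is_deg)
            summary["expression"] = {
                "n_tested": len(results), "n_deg": len(degs),
                "n_up": up, "n_down": len(degs) - up,
            }
            done.add(stage)
            summary["stages_run"].append(stage)

        # ---------------- enrichment ----------------
        stage = "enrichment"
        if _stage_guard(config, stage, done):
            annotation = enrichment.read_annotation(outdir / "synth" / "annotation.tsv")
            table = enrichment.enrich_table(annotation, degs)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "n_terms_tested": table.attrs["n_terms_tested"],
                "n_significant": int((table["corrected_p"] <= 0.05).sum()),
            }
            done.add(stage)
            summary["stages_run"].append(stage)

        # ---------------- homology ----------------
        stage = "homology"
        families = []
        ortho_pairs: list[tuple[str, str]] = []
        if _stage_guard(config, stage, done):
            hitter = homology.blastn_hits if config.aligner == "blastn" else (
                lambda q, s: homology.sw_hits(q, s)
            )
            pseq, gseq = p_set.sequences, g_set.sequences
            between = homology.best_hits(
                hitter(pseq, gseq) + hitter(gseq, pseq), config.evalue_cutoff
            )
            best_within = {
                "P": homology.best_hits(hitter(pseq, pseq), config.evalue_cutoff),
                "G": homology.best_hits(hitter(gseq, gseq), config.evalue_cutoff),
            }
            families, venn = homology.build_families(
                best_within, between, {"P": pseq, "G": gseq},
                reciprocal_only=config.reciprocal_orthologs,
            )
            rows = [
                {"family_id": f.family_id, "genotype": g, "member": m}
                for f in families for g, ids in sorted(f.members.items()) for m in ids
            ]
            pd.DataFrame(rows).to_csv(outdir / "families.tsv", sep="\t", index=False)
            pd.DataFrame([venn]).to_csv(outdir / "venn.tsv", sep="\t", index=False)
            ortho_pairs = sorted(
                {pair for f in families for pair in f.ortholog_pairs}
            )
            summary["homology"] = venn
            done.add(stage)
            summary["stages_run"].append(stage)

        # ---------------- ssr ----------------
        stage = "ssr"
        if _stage_guard(config, stage, done):
            ssrs_p = ssrmine.detect_ssrs(
                p_set.sequences, config.ssr_thresholds, config.ssr_min_seq_len
            )
            ssrs_g = ssrmine.detect_ssrs(
                g_set.sequences, config.ssr_thresholds, config.ssr_min_seq_len
            )
            classes = ssrmine.classify_ssrs(ssrs_p)
            classes.to_csv(outdir / "ssr_classes.tsv", sep="\t", index=False)
            pairs = [(p, g) for p, g in ortho_pairs if p.startswith("P_")] + [
                (g, p) for p, g in ortho_pairs if p.startswith("G_")
            ]
            poly = ssrmine.match_polymorphic(ssrs_p, ssrs_g, pairs)
            primers, flagged = ssrmine.export_primer_regions(poly)
            primers.to_csv(outdir / "primer_regions.tsv", sep="\t", index=False)
            summary["ssr"] = {
                "n_loci_P": len(ssrs_p), "n_loci_G": len(ssrs_g),
                "n_polymorphic": len(poly),
                "n_primer_rule": int(sum(p.passes_primer_rule for p in poly)),
                "n_flagged": len(flagged),
            }
            done.add(stage)
            summary["stages_run"].append(stage)

        # ---------------- snp ----------------
        stage = "snp"
        if _stage_guard(config, stage, done):
            records = snpmine.read_snp_table(outdir / "synth" / "snp_calls.tsv")
            kept = snpmine.filter_snps(
                records, config.snp_min_depth, config.snp_min_score, config.snp_min_spacing
            )
            table = snpmine.classify_substitutions(kept)
            table.to_csv(outdir / "snp_classes.tsv", sep="\t", index=False)
            summary["snp"] = {
                "n_input": len(records), "n_kept": len(kept),
                "transition_fraction": table.attrs["transition_fraction"],
            }
            done.add(stage)
            summary["stages_run"].append(stage)

        # ---------------- diversity ----------------
        stage = "diversity"
        if _stage_guard(config, stage, done):
            matrix = popdiv.GenotypeMatrix.read_csv(outdir / "synth" / "genotypes.csv")
            stats = popdiv.all_locus_stats(matrix)
            stats.to_csv(outdir / "locus_stats.tsv", sep="\t", index=False)
            boot = popdiv.bootstrap(matrix, B=config.bootstrap_B, seed=config.seed)
            (outdir / "tree.nwk").write_text(boot.newick + "\n")
            summary["diversity"] = {
                "n_markers": len(matrix.markers),
                "n_accessions": len(matrix.accessions),
                "mean_PIC": float(stats["PIC"].mean()),
                "mean_GD": float(stats["GD"].mean()),
                "bootstrap_B": config.bootstrap_B,
            }
            done.add(stage)
            summary["stages_run"].append(stage)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    log.info("pipeline complete: %s", ", ".join(summary["stages_run"]))
    log.removeHandler(handler)
    handler.close()
    return summary
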