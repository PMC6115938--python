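"""End-to-end orchestration over a fixture bundle or equivalent inputs.

``run_all`` executes every stage in dependency order on the files of a
bundle directory (the layout :func:`ensipipe.simulate.write_fixture_bundle`
writes, which is also the layout real inputs can be dropped into) and
returns a structured report: per-stage outputs, the effective parameter
snapshot, warnings, and wall time. All scientific fields of the report are
deterministic given the config and inputs; wall times are not compared.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import yaml

from . import assembly, fba, homology, merge, pangenome, symbiosis
from .config import PipelineConfig
from .errors import DataError, EnsipipeError, StageError
from .fba import MediumSpec
from .models import MetabolicModel


def _read_ortholog_map(path: Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                k, v = line.rstrip("\n").split("\t")[:2]
                out[k] = v
    return out


def run_all(config: PipelineConfig, input_dir: str | Path,
            out_dir: str | Path | None = None) -> dict:
    """Run assembly QC, ANI, BBH/AAI, pangenome analytics, COG comparison,
    model merge, FBA carbon screen and symbiosis classification on a bundle
    directory. A missing file or failed stage aborts with an error naming
    the stage."""
    input_dir = Path(input_dir)
    report: dict = {"parameters": config.to_dict(), "stages": {}, "warnings": []}
    t0 = time.time()

    def require(name: str) -> Path:
        p = input_dir / name
        if not p.exists():
            raise DataError(f"missing input file: {p}")
        return p

    stage = "assembly_qc"
    try:
        scaffolds = assembly.read_fasta_scaffolds(require("assembly.fasta"),
                                                  require("coverage.tsv"))
        kept = assembly.filter_scaffolds(scaffolds, config.scaffold_min_coverage,
                                         config.scaffold_min_length)
        stats = assembly.compute_stats(kept) if kept else None
        report["stages"][stage] = {
            "n_input_scaffolds": len(scaffolds),
            "n_kept_scaffolds": len(kept),
            "stats": stats.to_dict() if stats else None,
        }

        stage = "ani"
        genome_a = [s.sequence for s in assembly.read_fasta_scaffolds(require("genomeA.fasta"))]
        genome_b = [s.sequence for s in assembly.read_fasta_scaffolds(require("genomeB.fasta"))]
        ani = homology.averaged_ani(genome_a, genome_b, config.ani_fragment_length,
                                    config.ani_min_fragment_identity)
        report["stages"][stage] = {
            "one_way_ab": ani.one_way_ab, "one_way_ba": ani.one_way_ba,
            "averaged": ani.averaged, "n_fragments_mapped": ani.n_fragments_mapped,
        }

        stage = "bbh_aai"
        hits_ab = homology.read_hit_table(require("hits_ab.tsv"))
        hits_ba = homology.read_hit_table(require("hits_ba.tsv"))
        pairs = homology.bidirectional_best_hits(hits_ab, hits_ba,
                                                 config.bbh_min_identity,
                                                 config.bbh_min_coverage)
        aai = homology.compute_aai(hits_ab, hits_ba, config.aai_min_identity,
                                   config.aai_min_coverage, config.aai_max_evalue)
        report["stages"][stage] = {"n_bbh_pairs": len(pairs), "aai": aai}

        stage = "pangenome"
        matrix = pangenome.PresenceAbsenceMatrix.from_roary_csv(
            require("gene_presence_absence.csv"))
        focal = matrix.strains[0]
        core = pangenome.core_families(matrix)
        uniq = pangenome.unique_families(matrix, focal)
        venn_focal = matrix.strains[:min(4, len(matrix.strains))]
        venn = pangenome.venn_partition(matrix, venn_focal)
        gene_map = {fam: by_strain[focal]
                    for fam, by_strain in matrix.representative_gene.items()
                    if focal in by_strain}
        locations = pangenome.read_gene_locations_gff3(require("focal_genes.gff3"))
        islands = pangenome.detect_islands(uniq, gene_map, locations,
                                           config.island_min_genes,
                                           config.island_max_gap)
        report["stages"][stage] = {
            "focal_strain": focal,
            "n_core_families": len(core),
            "n_unique_families": len(uniq),
            "venn": {"&".join(sorted(k)): v for k, v in sorted(
                venn.items(), key=lambda kv: sorted(kv[0]))},
            "n_islands": len(islands),
            "islands": [i.__dict__ for i in islands],
        }

        stage = "cog_compare"
        ann1 = pangenome.read_cog_annotations(require("cog_strain1.tsv"))
        ann2 = pangenome.read_cog_annotations(require("cog_strain2.tsv"))
        prof1 = pangenome.cog_profile(ann1, "strain1")
        prof2 = pangenome.cog_profile(ann2, "strain2")
        comps = pangenome.compare_cog_profiles(prof1, prof2, config.fisher_alpha)
        report["stages"][stage] = {
            "n_categories": len(comps),
            "n_significant": sum(c.significant for c in comps),
            "min_p": min(c.p_value for c in comps),
        }

        stage = "model_merge"
        draft = MetabolicModel.from_json(require("draft_model.json"))
        donor = MetabolicModel.from_json(require("donor_model.json"))
        omap = _read_ortholog_map(require("ortholog_map.tsv"))
        merged, merge_report = merge.merge_pipeline(draft, [(donor, omap)])
        report["stages"][stage] = {
            "final_n_genes": len(merged.genes),
            "final_n_reactions": len(merged.reactions),
            "final_n_metabolites": len(merged.metabolites),
            "report": merge_report.to_dict(),
        }

        stage = "fba_screen"
        medium = MediumSpec.from_yaml(require("medium.yaml"))
        with open(require("panel.yaml")) as fh:
            panel = yaml.safe_load(fh)["panel"]
        growth = fba.solve_fba(merged, medium)
        screen = fba.carbon_source_screen(merged, medium, panel,
                                          config.uptake_rate, config.growth_epsilon)
        report["stages"][stage] = {
            "base_medium_objective": growth.objective_value,
            "n_tested": screen.n_tested,
            "n_growth": screen.n_growth,
            "per_source": {k: {"objective": v[0], "grows": v[1]}
                           for k, v in sorted(screen.per_source.items())},
        }

        stage = "symbiosis"
        seed_hits = symbiosis.read_tblout(require("symbiosis_seed.tbl"))
        scan_hits = symbiosis.read_tblout(require("symbiosis_scan.tbl"))
        candidates = symbiosis.collect_candidates(seed_hits)
        top = symbiosis.top_hit_per_query(
            [h for h in scan_hits if h.query_id in candidates])
        calls = symbiosis.classify(top)
        presence = symbiosis.summarize_presence(calls)
        report["stages"][stage] = {
            "n_candidates": len(candidates),
            "calls": {c.query_id: c.label for c in calls},
            "presence": presence,
        }
    except EnsipipeError as e:
        raise StageError(f"stage {stage!r} failed: {e}") from e

    report["wall_time_s"] = time.time() - t0
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
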