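"""High-level orchestration shared by the CLI and the test suite."""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import degradation, io, mining, phylo, structure
from .config import RunConfig
from .synth import ElementBlueprint, GenomeRecord, make_profile_library, plant_elements

logger = logging.getLogger(__name__)


def simulate(cfg: RunConfig, seed: int | None = None):
    """Generate genomes + truths + the profile library from a config."""
    seed = cfg.seed if seed is None else seed
    library = make_profile_library(seed)
    genomes, truths = [], []
    for gi, gcfg in enumerate(cfg.genomes):
        blueprints = []
        bi = 0
        for b in gcfg.elements:
            for _ in range(b.count):
                blueprints.append(
                    ElementBlueprint(
                        structure=b.structure,
                        ltr_length=b.ltr_length,
                        ltr_divergence=b.ltr_divergence,
                        domain_divergence=b.domain_divergence,
                        degrade_native_rh=b.degrade_native_rh,
                        degrade_distal_arh=b.degrade_distal_arh,
                        seed=bi,
                    )
                )
                bi += 1
        genome, truth = plant_elements(
            gcfg.length, blueprints, gc=gcfg.gc, seed=seed + 1000 * (gi + 1),
            library=library, genome_id=gcfg.genome_id, taxon=gcfg.taxon,
        )
        genomes.append(genome)
        truths.extend(truth)
    return library, genomes, truths


def annotate_genome(
    genome: GenomeRecord,
    profiles: list[mining.DomainProfile],
    cfg: RunConfig | None = None,
) -> list[tuple[mining.ElementChain, structure.StructureCall]]:
    """Mine, chain, find LTRs, assign ORFs and classify one genome."""
    cfg = cfg or RunConfig()
    hits = mining.mine_domains(genome, profiles, min_bits_frac=cfg.min_bits_frac)
    chains = mining.chain_hits(hits, max_gap=cfg.max_gap)
    out = []
    for chain in chains:
        mining.find_ltrs(
            genome, chain, flank=cfg.flank,
            min_len=cfg.ltr_min_len, min_identity=cfg.ltr_min_identity,
        )
        structure.assign_orfs(genome, chain, min_orf_aa=cfg.min_orf_aa)
        call = structure.classify_structure(chain, arh_linker_max=cfg.arh_linker_max)
        out.append((chain, call))
    return out


def assess_degradation(
    annotated: list[tuple[mining.ElementChain, structure.StructureCall]],
    profiles: list[mining.DomainProfile],
    degraded_threshold: int = 1,
) -> list[tuple[str, str, degradation.RHAssessment]]:
    """RH/ARH catalytic-core assessments with roles resolved per structure."""
    by_name = {p.name: p for p in profiles}
    out = []
    for chain, call in annotated:
        rh = chain.hit_for("RH")
        if rh is not None and "RH" in by_name:
            out.append(
                (call.label, "native_RH",
                 degradation.catalytic_core_state(
                     rh.matched_aa, by_name["RH"],
                     domain_id=f"{chain.chain_id}|RH",
                     degraded_threshold=degraded_threshold))
            )
        arh_hits = [h for h in chain.hits if h.profile_name == "ARH"]
        for k, h in enumerate(arh_hits):
            role = "aRH_proximal" if k == 0 else "aRH_distal"
            if "ARH" in by_name:
                out.append(
                    (call.label, role,
                     degradation.catalytic_core_state(
                         h.matched_aa, by_name["ARH"],
                         domain_id=f"{chain.chain_id}|ARH{k}",
                         degraded_threshold=degraded_threshold))
                )
    return out


def rt_phylogeny(
    annotated_by_genome: dict[str, list[tuple[mining.ElementChain, structure.StructureCall]]],
    cfg: RunConfig | None = None,
    seed: int = 0,
    domain: str = "RT",
) -> tuple[phylo.SupportedTree | None, phylo.MultipleAlignment | None]:
    """Bootstrap-supported NJ tree of one domain across all chains."""
    cfg = cfg or RunConfig()
    seqs = {}
    for chains in annotated_by_genome.values():
        for chain, _call in chains:
            hit = chain.hit_for(domain)
            if hit is not None:
                seqs[chain.chain_id] = hit.matched_aa
    if len(seqs) < 3:
        return None, None
    aln = phylo.progressive_align(seqs)
    tree = phylo.bootstrap_support(
        aln, n_reps=cfg.n_reps, seed=seed, poisson_correct=cfg.poisson_correct
    )
    return tree, aln


def build_report(
    annotated_by_genome: dict[str, list[tuple[mining.ElementChain, structure.StructureCall]]],
    profiles: list[mining.DomainProfile],
    cfg: RunConfig,
    out_dir: str | Path,
    taxon_map: dict[str, str] | None = None,
    species_tree: phylo.SupportedTree | None = None,
    taxon_states: dict[str, set[str]] | None = None,
    seed: int = 0,
) -> dict:
    """Produce frequency tables, degradation summary, trees, filter decisions
    and the parsimony scenario; returns a summary dict and writes TSV/newick
    plus a markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxon_map = taxon_map or {}
    summary: dict = {}

    all_annotated = [(g, c, call) for g, lst in annotated_by_genome.items() for c, call in lst]

    freq = structure.structure_frequency_table([(g, call) for g, _c, call in all_annotated])
    freq.to_csv(out / "structure_frequencies.tsv", sep="\t", index=False)
    summary["n_elements"] = len(all_annotated)

    assessments = []
    for g, lst in annotated_by_genome.items():
        assessments.extend(assess_degradation(lst, profiles, cfg.degraded_threshold))
    deg = degradation.degradation_report(assessments)
    deg.to_csv(out / "degradation_summary.tsv", sep="\t", index=False)

    tree, aln = rt_phylogeny(annotated_by_genome, cfg, seed=seed)
    clusters: list[frozenset[str]] = []
    monophyly = None
    if tree is not None:
        (out / "rt_tree.nwk").write_text(tree.newick() + "\n")
        clusters = phylo.credible_clusters(tree, threshold=cfg.support_threshold)
        arh_tips = {
            c.chain_id
            for _g, c, call in all_annotated
            if call.label in ("S1", "S2", "S3", "S4", "S5") and c.hit_for("RT") is not None
        }
        if arh_tips and arh_tips < tree.tips():
            mono, support = phylo.test_monophyly(tree, arh_tips)
            monophyly = {"monophyletic": bool(mono),
                         "support": None if support is None else float(support)}
    summary["credible_clusters"] = [sorted(c) for c in clusters]
    summary["arh_monophyly"] = monophyly

    lineage_ids = [c.chain_id for _g, c, _call in all_annotated]
    structures_map = {c.chain_id: call.label for _g, c, call in all_annotated}
    groups = {c.chain_id: taxon_map.get(g, g) for g, c, _call in all_annotated}
    artifact = {c.chain_id: (c.edge_truncated or c.ltr is None) for _g, c, _call in all_annotated}
    flags = phylo.compute_lineage_flags(lineage_ids, clusters, groups, structures_map, artifact)
    retained, removed = phylo.filter_lineages(flags)
    pd.DataFrame(
        [
            {"lineage_id": f.lineage_id, "c1_discordant_clustering": f.c1_discordant_clustering,
             "c2_unique_structure": f.c2_unique_structure,
             "c3_whole_contig_or_no_ltr": f.c3_whole_contig_or_no_ltr, "removed": f.removed}
            for f in flags
        ]
    ).to_csv(out / "lineage_filter.tsv", sep="\t", index=False)
    summary["n_retained"] = len(retained)
    summary["n_removed"] = len(removed)

    scenario = None
    if species_tree is not None:
        if taxon_states is None:
            taxon_states = defaultdict(set)
            for g, _c, call in all_annotated:
                taxon_states[taxon_map.get(g, g)].add(call.label)
        tips_with_states = {t: set(s) for t, s in taxon_states.items() if s}
        missing = species_tree.tips() - set(tips_with_states)
        if missing:
            logger.warning("species tree tips without observed structures: %s", sorted(missing))
        else:
            changes, states = phylo.fitch_parsimony(species_tree, tips_with_states)
            scenario = {
                "min_changes": changes,
                "root_states": sorted(states[species_tree.root]),
            }
    summary["scenario"] = scenario

    _write_markdown_report(out, cfg, freq, deg, summary)
    io.write_json(summary, out / "summary.json")
    return summary


def _write_markdown_report(out: Path, cfg: RunConfig, freq: pd.DataFrame,
                           deg: pd.DataFrame, summary: dict) -> None:
    lines = ["# ltrarch run report", ""]
    lines += ["## Thresholds", "", "```"]
    for k in ("min_bits_frac", "max_gap", "flank", "ltr_min_len", "ltr_min_identity",
              "min_orf_aa", "arh_linker_max", "identity_threshold",
              "degraded_threshold", "support_threshold", "n_reps"):
        lines.append(f"{k} = {getattr(cfg, k)}")
    lines.append("```")
    lines += ["", "## Structure frequencies", "", freq.to_markdown(index=False) if len(freq) else "(no elements)"]
    lines += ["", "## Catalytic-core degradation", "", deg.to_markdown(index=False) if len(deg) else "(no RH-type domains)"]
    if summary.get("arh_monophyly") is not None:
        m = summary["arh_monophyly"]
        lines += ["", f"ARH-bearing clade monophyletic: {m['monophyletic']} (support {m['support']})"]
    if summary.get("scenario") is not None:
        s = summary["scenario"]
        lines += ["", f"Parsimony scenario: {s['min_changes']} minimal changes; root states {s['root_states']}"]
    lines += ["", f"Lineages retained: {summary['n_retained']}, removed: {summary['n_removed']}", ""]
    (out / "report.md").write_text("\n".join(lines))
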