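"""End-to-end orchestration: simulate -> analyze -> report.

``run_all`` chains every stage on synthetic data with known ground truth:
genome simulation and read generation, k-mer subgenome attribution with
genome sizing, plastid maternity inference, homeolog ancestry tallying and
the co-expression screen.  It writes one deterministic JSON summary plus
per-stage TSVs; identical config + seed reproduce byte-identical output.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from polyorigin import coexpression, io, kmers, phylogeny, plastid, simdata


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sim_config(config: io.RunConfig) -> simdata.SimulationConfig:
    overrides = dict(config.simulate)
    overrides.setdefault("seed", config.seed)
    # YAML lists arrive as lists; the dataclass wants tuples
    for key in ("parent_labels", "topology_mix", "expression_samples"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    return simdata.SimulationConfig(**overrides)


def _stage_genomes(sim: simdata.SimulationConfig) -> dict:
    """Diploid progenitors, a maternal clade, the tetraploid, and reads."""
    import numpy as np

    rng_seed = sim.seed
    base = simdata.simulate_progenitors(
        sim.with_(parent_labels=(simdata.PATERNAL, "maternal_ancestor"))
    )
    # the two extant maternal tips diverge from the maternal ancestor
    tip_rng = np.random.default_rng(rng_seed + 1)
    half = sim.divergence_per_branch / 2
    tip1, _ = simdata.evolve_sequence(base.genomes["maternal_ancestor"], half, tip_rng)
    tip2, _ = simdata.evolve_sequence(base.genomes["maternal_ancestor"], half, tip_rng)
    genomes = {
        simdata.PATERNAL: base.genomes[simdata.PATERNAL],
        simdata.MATERNAL_TIP_1: tip1,
        simdata.MATERNAL_TIP_2: tip2,
    }
    hybrid = simdata.hybridize(
        genomes[simdata.PATERNAL],
        tip2,
        downsizing_fraction=sim.downsizing_fraction,
        seed=rng_seed + 2,
        block_size=sim.downsizing_block,
    )
    genomes[simdata.HYBRID] = hybrid.sequence
    reads = {
        label: simdata.simulate_reads(
            g, sim.coverage, sim.read_length, sim.error_rate,
            seed=rng_seed + 10 + i, name_prefix=label,
        )
        for i, (label, g) in enumerate(sorted(genomes.items()))
    }
    truth_fraction = 100.0 * hybrid.subgenome_length(0) / len(hybrid.sequence)
    return {
        "genomes": genomes,
        "reads": reads,
        "hybrid": hybrid,
        "truth_paternal_fraction": truth_fraction,
    }


def _stage_kmers(config: io.RunConfig, genomes_out: dict, out: Path) -> dict:
    reads = genomes_out["reads"]
    counts = {
        label: kmers.count_kmers([r.sequence for r in rs], k=config.k, label=label)
        for label, rs in reads.items()
    }
    spectrum = counts[simdata.HYBRID].spectrum()
    size = kmers.estimate_genome_size(spectrum, config.size_cutoff)
    sets = {
        label: c.filtered_set(config.d_min, config.d_max)
        for label, c in counts.items()
    }
    partition = kmers.venn_partition(list(sets.values()))
    report = kmers.attribute_subgenome(
        sets[simdata.HYBRID],
        sets[simdata.PATERNAL],
        [sets[simdata.MATERNAL_TIP_1], sets[simdata.MATERNAL_TIP_2]],
        hybrid_size_gb=size.size_bases / 1e9,
    )
    io.write_tsv(pd.DataFrame(spectrum.to_rows()), out / "kmer_spectrum.tsv", index=False)
    io.write_tsv(pd.DataFrame(partition.to_rows()), out / "kmer_venn.tsv", index=False)
    io.write_report(report.to_dict(), out / "kmer_attribution.json")
    return {
        "genome_size_estimate_bases": round(size.size_bases),
        "modal_depth": size.modal_depth,
        "error_cutoff": size.cutoff,
        "paternal_fraction_percent": round(report.paternal_fraction, 2),
        "maternal_fraction_percent": round(report.maternal_fraction, 2),
        "truth_paternal_fraction_percent": round(
            genomes_out["truth_paternal_fraction"], 2
        ),
        "n_diagnostic": report.n_paternal_diagnostic + report.n_maternal_diagnostic,
    }


def _stage_plastid(sim: simdata.SimulationConfig, out: Path) -> dict:
    psim = simdata.simulate_plastid_snps(sim)
    table = plastid.infer_maternal(
        psim.snp_sets[simdata.HYBRID],
        psim.snp_sets[simdata.PATERNAL],
        [psim.snp_sets[simdata.MATERNAL_TIP_1], psim.snp_sets[simdata.MATERNAL_TIP_2]],
    )
    io.write_report(table.to_dict(), out / "plastid_maternity.json")
    return {
        "call_lineage": table.call.lineage,
        "call_species": table.call.species,
        "truth_maternal": psim.maternal_truth,
        "call_correct": table.call.species == psim.maternal_truth,
    }


def _stage_homeologs(sim: simdata.SimulationConfig, tau: float, out: Path) -> dict:
    osim = simdata.simulate_ortholog_groups(sim)
    rule = osim.rule
    retained, attrition = phylogeny.filter_by_composition(osim.groups, rule)
    assignments = []
    n_untrimmable = n_gap_dropped = 0
    for group in retained:
        try:
            aln = phylogeny.trim_alignment(group.alignment)
        except phylogeny.TrimError:
            n_untrimmable += 1
            continue
        if not phylogeny.gap_filter(aln, tau):
            n_gap_dropped += 1
            continue
        labels, dist = phylogeny.p_distance_matrix(aln)
        tree = phylogeny.neighbor_joining(dist, labels)
        assignments.append(
            phylogeny.assign_ancestry(tree, group.species_of(), rule)
        )
    attrition |= {"dropped_untrimmable": n_untrimmable, "dropped_gap_filter": n_gap_dropped}
    result = phylogeny.tally(assignments, rule, attrition)
    io.write_report(result.to_dict(), out / "homeolog_tally.json")
    truth_counts = (
        osim.truth[~osim.truth.corrupted]
        .loc[lambda t: t.gap_class != "heavy"]
        .topology.value_counts()
        .to_dict()
    )
    return {
        "tally": {k: int(v) for k, v in sorted(result.counts.items())},
        "informative_total": result.informative_total,
        "attrition": attrition,
        "truth_counts": {k: int(v) for k, v in sorted(truth_counts.items())},
    }


def _stage_coexpression(
    sim: simdata.SimulationConfig, config: io.RunConfig, out: Path
) -> dict:
    esim = simdata.simulate_expression(sim)
    hits = coexpression.correlate(esim.expression, esim.metabolite, config.transform)
    result = coexpression.screen(hits, config.r_min)
    io.write_tsv(result.candidates, out / "coexpression_hits.tsv")
    planted_r = {
        g: round(float(hits.loc[g, "r"]), 4)
        for g in esim.planted_ids
        if g in hits.index
    }
    return {
        "n_candidates": len(result.candidates),
        "planted_recovered": sorted(
            g for g in esim.planted_ids if g in result.candidates.index
        ),
        "planted_r": planted_r,
        "r_min": config.r_min,
    }


def run_all(config: io.RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage on synthetic data; returns (and writes) the summary."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = _sim_config(config)
    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    io.log("simulate", "generating genomes and reads")
    try:
        genomes_out = _stage_genomes(sim)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    for stage, fn in (
        ("kmer_attribution", lambda: _stage_kmers(config, genomes_out, out)),
        ("plastid_maternity", lambda: _stage_plastid(sim, out)),
        ("homeolog_phylogeny", lambda: _stage_homeologs(sim, config.tau, out)),
        ("coexpression_screen", lambda: _stage_coexpression(sim, config, out)),
    ):
        io.log(stage, "running")
        try:
            summary[stage] = fn()
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
    io.write_report(summary, out / "summary.json")
    io.log("done", f"summary written to {out / 'summary.json'}")
    return summary
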