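"""End-to-end orchestration: simulate -> IR -> synteny -> variants ->
comparative tables -> phylogeny, from one configuration mapping.

The run writes per-species FASTA/GFF3, the structural report, synteny
segments, a multi-sample VCF, the density/coding-SNP/MNP tables, window
densities, the bootstrapped tree, and a JSON manifest.  All randomness
derives from the single configured seed, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .core import (
    AnalysisConfig,
    CircularGenome,
    GenomeAnnotation,
    PlastcompError,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
    write_vcf,
)
from .comparative import (
    build_share_matrix,
    density_table,
    find_mnp_pairs,
    ns_summary,
)
from .ir_repeats import (
    compare_ir_boundaries,
    find_inverted_repeats,
    ir_boundary_gene_order,
    ir_report_rows,
)
from .phylo import bootstrap_support, concatenate, align_gene, extract_shared_cds
from .simulate import SimParams, evolve, generate_ancestor, write_truth
from .synteny import synteny_map, write_segments_tsv
from .variants import call_variants, window_density, write_window_tsv

logger = logging.getLogger("plastcomp")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_inputs(config: dict) -> tuple[dict[str, CircularGenome],
                                       dict[str, GenomeAnnotation],
                                       Optional[object]]:
    """Genomes + annotations from the simulate block or from files."""
    truth = None
    if "simulate" in config:
        sim_cfg = dict(config["simulate"])
        params = SimParams(**sim_cfg)
        ancestor, ann = generate_ancestor(params)
        leaves, truth = evolve(ancestor, ann, params)
        genomes = {name: g for name, (g, _a) in leaves.items()}
        annotations = {name: a for name, (_g, a) in leaves.items()}
        return genomes, annotations, truth
    genomes = {}
    annotations = {}
    for entry in config["species"]:
        name = entry["name"]
        recs = read_fasta(entry["fasta"])
        if len(recs) != 1:
            raise PlastcompError(f"{entry['fasta']}: expected one record")
        genome = CircularGenome(id=name, seq=recs[0].seq)
        if "gff3" not in entry:
            raise PlastcompError(f"missing annotation for species {name}")
        annotations[name] = read_gff3(entry["gff3"], genome)
        genomes[name] = genome
    return genomes, annotations, truth


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = AnalysisConfig(**config.get("analysis", {}))
    manifest: dict = {"version": __version__, "config": config,
                      "stages": {}, "outputs": {}}
    t_all = time.time()

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time() - t_all}
        return time.time()

    def done(name, t0):
        manifest["stages"][name]["seconds"] = round(time.time() - t0, 3)

    try:
        t0 = stage("inputs")
        genomes, annotations, truth = load_inputs(config)
        species = sorted(genomes)
        reference = config.get("reference", species[0])
        if reference not in genomes:
            raise PlastcompError(f"reference species {reference!r} not present")
        for name in species:
            write_fasta([genomes[name]], out / f"{name}.fasta")
            write_gff3(annotations[name], out / f"{name}.gff3")
        if truth is not None:
            write_truth(truth, out / "truth", reference_leaf=reference)
        done("inputs", t0)

        t0 = stage("ir")
        orders = []
        rows = []
        for name in species:
            ir = find_inverted_repeats(genomes[name], min_len=acfg.ir_min_len,
                                       max_mismatch_frac=acfg.ir_max_mismatch_frac)
            order = (ir_boundary_gene_order(ir, annotations[name], species=name)
                     if ir else None)
            if order:
                orders.append(order)
            rows.append(ir_report_rows(name, genomes[name], ir, order))
        reports = compare_ir_boundaries(orders) if len(orders) >= 2 else []
        by_species = {r.species: r.description for r in reports}
        with open(out / "structure.tsv", "w") as fh:
            fh.write("species\tlength_bp\tir_length_bp\tboundaries\t"
                     "rearrangements\n")
            for row in rows:
                fh.write("\t".join([
                    row["species"], str(row["length_bp"]),
                    str(row["ir_length_bp"]), row["boundaries"],
                    by_species.get(row["species"], ""),
                ]) + "\n")
        done("ir", t0)

        t0 = stage("synteny")
        ref_genome = genomes[reference]
        segments_by_species = {}
        for name in species:
            if name == reference:
                continue
            segs, bps = synteny_map(ref_genome, genomes[name], acfg)
            segments_by_species[name] = segs
            write_segments_tsv(segs, bps, out / f"synteny_{name}.tsv")
        done("synteny", t0)

        t0 = stage("variants")
        all_calls = []
        for name in species:
            if name == reference:
                continue
            calls = call_variants(ref_genome, genomes[name],
                                  segments_by_species[name], acfg,
                                  annotation=annotations[reference],
                                  species=name)
            all_calls.extend(calls)
        all_calls.sort(key=lambda c: (c.pos, c.ref_allele, c.alt_allele))
        write_vcf(all_calls, ref_genome, out / "variants.vcf",
                  species_order=[s for s in species if s != reference])
        densities = window_density(all_calls, ref_genome.length,
                                   acfg.window_size)
        write_window_tsv(densities, out / "window_density.tsv")
        done("variants", t0)

        t0 = stage("compare")
        share = build_share_matrix(all_calls)
        ns = ns_summary(all_calls, share, annotations[reference], ref_genome,
                        acfg.genetic_code_table)
        mnp = find_mnp_pairs(all_calls, annotations[reference])
        dens = density_table(all_calls, {sp: annotations[sp]
                                         for sp in species if sp != reference})
        _write_share(share, out / "share_matrix.tsv")
        _write_ns(ns, out / "coding_snps.tsv")
        _write_mnp(mnp, out / "mnp_pairs.tsv")
        _write_density(dens, out / "density.tsv")
        from .comparative import compare_trna_positions, segment_position_mapper

        maps = {name: segment_position_mapper(segs)
                for name, segs in segments_by_species.items()}
        clusters = compare_trna_positions(annotations, maps, reference,
                                          tolerance=acfg.trna_cluster_tolerance)
        with open(out / "trna_clusters.tsv", "w") as fh:
            fh.write("ref_position\tn_species\tmembers\torphan\tunplaced\n")
            for cl in clusters:
                members = ",".join(f"{sp}:{name}@{pos}"
                                   for sp, (name, pos)
                                   in sorted(cl.members.items()))
                fh.write(f"{cl.ref_position}\t{len(cl.members)}\t{members}\t"
                         f"{int(cl.orphan)}\t{int(cl.unplaced)}\n")
        done("compare", t0)

        t0 = stage("phylo")
        shared = extract_shared_cds(annotations, genomes)
        alignments = {g: align_gene(seqs, reference)
                      for g, seqs in shared.items()}
        concat = concatenate(alignments)
        reps = config.get("analysis", {}).get("bootstrap_reps",
                                              acfg.bootstrap_reps)
        tree, supports = bootstrap_support(concat, reps=reps,
                                           seed=acfg.seed,
                                           gamma_shape=acfg.gamma_shape)
        with open(out / "tree.nwk", "w") as fh:
            fh.write(tree.newick + "\n")
        with open(out / "supports.tsv", "w") as fh:
            fh.write("bipartition\tsupport_percent\n")
            for bp, s in sorted(supports.items(),
                                key=lambda kv: sorted(kv[0])):
                fh.write(",".join(sorted(bp)) + f"\t{s:.1f}\n")
        with open(out / "alignment.fasta", "w") as fh:
            for taxon in concat.taxa:
                fh.write(f">{taxon}\n{concat.rows[taxon]}\n")
        with open(out / "partitions.tsv", "w") as fh:
            fh.write("gene\tstart\tend\n")
            for g, (s, e) in concat.gene_partitions.items():
                fh.write(f"{g}\t{s}\t{e}\n")
        done("phylo", t0)
    except PlastcompError as exc:
        current = [k for k, v in manifest["stages"].items()
                   if "seconds" not in v]
        stage_name = current[-1] if current else "?"
        raise PlastcompError(f"stage {stage_name}: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _write_share(share, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tsnps\n")
        for sp, n in sorted(share.unique_counts.items()):
            fh.write(f"{sp}\t{n}\n")
        for pair, n in sorted(share.pair_counts.items(),
                              key=lambda kv: sorted(kv[0])):
            fh.write(",".join(sorted(pair)) + f"\t{n}\n")
        fh.write(f"multi\t{share.multi_counts}\n")


def _write_ns(ns, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tall\tsynonymous\tnonsynonymous\tns_percent\n")
        for r in ns.rows + [ns.sum_row]:
            fh.write(f"{r.category}\t{r.all}\t{r.synonymous}\t"
                     f"{r.nonsynonymous}\t{r.ratio_percent}\n")
        fh.write(f"different_codon_changes\t\t\t{ns.different_codon_changes}\t\n")


def _write_mnp(mnp, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tgenic\tintergenic\n")
        for cat, (g, i) in sorted(mnp.rows.items(), key=lambda kv: str(kv[0])):
            name = ",".join(sorted(cat)) if isinstance(cat, frozenset) else str(cat)
            fh.write(f"{name}\t{g}\t{i}\n")
        fh.write(f"All\t{mnp.genic_total}\t{mnp.intergenic_total}\n")


def _write_density(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tgenic_snps\tintergenic_snps\tgenic_bp\t"
                 "intergenic_bp\tintergenic_genic_ratio\tsnp_per_kb_genic\t"
                 "snp_per_kb_intergenic\n")
        for r in rows:
            fh.write(f"{r.species}\t{r.genic_snps}\t{r.intergenic_snps}\t"
                     f"{r.genic_bp}\t{r.intergenic_bp}\t"
                     f"{r.intergenic_genic_ratio}\t{r.snp_per_kb_genic}\t"
                     f"{r.snp_per_kb_intergenic}\n")
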