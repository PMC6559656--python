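"""End-to-end orchestration: simulate/load -> phase -> LD -> rho profile ->
selection table -> tree -> association, aggregated into one JSON report.

Stage failures halt their downstream dependents but independent stages still
run; the report records per-stage status.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import asdict
from typing import Any, Optional

from . import io as ppio
from .assoc import CountLevel, associate, carrier_table
from .coalescent import RecombMap
from .core import (
    GenotypeMatrix,
    HaplotypeSet,
    Marker,
    Phenotype,
    region_summary,
)
from .ld import find_blocks, ld_matrix, region_mean_ld
from .phase import count_distinct_haplotypes, em_phase
from .phylo import distance_matrix, haplotypes_to_sequences, nj_tree
from .recomb import TwoLocusLookup, build_lookup, composite_rho, rmin_hudson_kaplan
from .selection import selection_stats
from .simulate import SimConfig, diploidize, simulate_haplotypes

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("phase", "ld", "recomb", "selection", "phylo", "assoc")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _simulate_inputs(config: dict, seed: int):
    sim = config.get("simulate", {})
    hotspots = tuple(
        (h["center_bp"], h["width_bp"], h["factor"])
        for h in sim.get("hotspots", [])
    )
    rmap = RecombMap(
        sim.get("region_length_bp", 18_000),
        sim.get("background_rho_per_kb", 0.5),
        hotspots,
    )
    sc = SimConfig(
        n_chromosomes=sim.get("n_chromosomes", 60),
        theta_per_kb=sim.get("theta_per_kb", 1.5),
        recomb_map=rmap,
        vntr_step_rate=sim.get("vntr_step_rate", 2.0),
        seed=seed,
    )
    out = simulate_haplotypes(sc)
    gm = diploidize(
        out.haplotypes,
        case_fraction=sim.get("case_fraction", 0.5),
        seed=seed + 1,
    )
    return out.markers, gm, sc.region_length_bp


def run_pipeline(config: dict, out_dir: str, seed: int = 0) -> dict:
    """Run the configured stages and write ``report.json`` under ``out_dir``.

    ``config`` keys: ``input`` (variant-table path) or ``simulate`` block;
    ``stages`` (subset of phase/ld/recomb/selection/phylo/assoc); optional
    per-stage parameter blocks.  Returns the report dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    report: dict[str, Any] = {"stages": {}, "results": {}}
    failures: list[str] = []

    if config.get("input"):
        markers, gm = ppio.read_variant_table(config["input"])
        length_bp = int(config.get("length_bp", 18_000))
    else:
        markers, gm, length_bp = _simulate_inputs(config, seed)
        ppio.write_variant_table(
            os.path.join(out_dir, "genotypes.tsv"), markers, gm
        )
    summary = region_summary(markers, gm, length_bp)
    report["results"]["region_summary"] = {
        "n_markers": summary.n_markers,
        "length_bp": summary.length_bp,
        "density_per_kb": round(summary.density_per_kb, 4),
        "maf": {k: round(v, 6) for k, v in summary.maf.items()},
    }

    haps: Optional[HaplotypeSet] = None
    if "phase" in stages:
        params = config.get("phase", {})
        try:
            res = em_phase(
                gm,
                tol=params.get("tol", 1e-6),
                max_iter=params.get("max_iter", 1000),
                n_restarts=params.get("restarts", 3),
                seed=seed,
                ligate=len(gm.marker_ids) > 30,
            )
            haps = res.phased
            n_distinct, mult = count_distinct_haplotypes(haps)
            report["stages"]["phase"] = "ok"
            report["results"]["phase"] = {
                "n_iter": res.n_iter,
                "converged": res.converged,
                "n_distinct_haplotypes": n_distinct,
                "max_multiplicity": max(mult.values()),
                "dropped_subjects": res.dropped_subjects,
            }
            ppio.write_haplotype_table(
                os.path.join(out_dir, "phased.tsv"), markers, haps,
                phenotype=gm.phenotype,
            )
        except Exception as exc:  # stage isolation by design
            logger.exception("phase stage failed")
            report["stages"]["phase"] = f"failed: {exc}"
            failures.append("phase")

    downstream_ok = haps is not None

    if "ld" in stages:
        if not downstream_ok:
            report["stages"]["ld"] = "skipped: no phased haplotypes"
        else:
            try:
                params = config.get("ld", {})
                matrix = ld_matrix(haps)
                dp, r2, n_pairs = region_mean_ld(matrix)
                blocks = find_blocks(haps) if params.get("blocks", True) else []
                report["stages"]["ld"] = "ok"
                report["results"]["ld"] = {
                    "mean_D_prime": round(dp, 4),
                    "mean_r2": round(r2, 4),
                    "n_pairs": n_pairs,
                    "n_undefined_pairs": matrix.n_undefined,
                    "blocks": [
                        {
                            "start": b.start_marker,
                            "end": b.end_marker,
                            "n_markers": len(b.marker_ids),
                        }
                        for b in blocks
                    ],
                }
            except Exception as exc:
                logger.exception("ld stage failed")
                report["stages"]["ld"] = f"failed: {exc}"
                failures.append("ld")

    if "recomb" in stages:
        if not downstream_ok:
            report["stages"]["recomb"] = "skipped: no phased haplotypes"
        else:
            try:
                params = config.get("recomb", {})
                lookup_path = params.get("lookup")
                if lookup_path and os.path.exists(lookup_path):
                    lookup = TwoLocusLookup.from_json(lookup_path)
                else:
                    lookup = build_lookup(
                        haps.n_chromosomes,
                        reps=params.get("lookup_reps", 2000),
                        seed=seed,
                    )
                    if lookup_path:
                        lookup.to_json(lookup_path)
                profile = composite_rho(
                    haps,
                    markers,
                    lookup,
                    window_bp=params.get("window_bp", 2000.0),
                    step_bp=params.get("step_bp", 500.0),
                    max_pair_span_bp=params.get("max_pair_span_bp", 5000.0),
                )
                rmin, _ = rmin_hudson_kaplan(haps)
                report["stages"]["recomb"] = "ok"
                report["results"]["recomb"] = {
                    "background_rho_per_kb": round(profile.background, 4),
                    "rmin": rmin,
                    "windows": [
                        {
                            "start": s, "end": e,
                            "rho_per_kb": None if math.isnan(r) else round(r, 4),
                            "n_pairs": np_,
                        }
                        for s, e, r, np_ in profile.windows
                    ],
                    "hotspots": [asdict(h) for h in profile.hotspots],
                }
            except Exception as exc:
                logger.exception("recomb stage failed")
                report["stages"]["recomb"] = f"failed: {exc}"
                failures.append("recomb")

    if "selection" in stages:
        if not downstream_ok:
            report["stages"]["selection"] = "skipped: no phased haplotypes"
        else:
            try:
                stats = selection_stats(haps, markers, L=length_bp)
                report["stages"]["selection"] = "ok"
                report["results"]["selection"] = {
                    "n": stats.n,
                    "S": stats.S,
                    "a1": round(stats.a1, 4),
                    "theta_per_site": stats.theta_per_site,
                    "pi_per_site": stats.pi_per_site,
                    "tajima_D": stats.tajima_D,
                    "by_class": {
                        vc.value: {
                            "S": cs.S,
                            "h": round(cs.mean_h, 4),
                            "theta_per_site": cs.theta_per_site,
                            "pi_per_site": cs.pi_per_site,
                            "tajima_D": cs.tajima_D,
                        }
                        for vc, cs in stats.by_class.items()
                    },
                }
            except Exception as exc:
                logger.exception("selection stage failed")
                report["stages"]["selection"] = f"failed: {exc}"
                failures.append("selection")

    if "phylo" in stages:
        if not downstream_ok:
            report["stages"]["phylo"] = "skipped: no phased haplotypes"
        else:
            try:
                params = config.get("phylo", {})
                _, mult = count_distinct_haplotypes(haps)
                distinct = sorted(mult)
                labels = [f"hap{i + 1}" for i in range(len(distinct))]
                distinct_set = HaplotypeSet(
                    haplotypes=[h for h in distinct for _ in (0, 1)],
                    subject_of=[
                        lab for lab in labels for _ in (0, 1)
                    ],
                    marker_ids=list(haps.marker_ids),
                    source=haps.source,
                )
                seqs, _mapping = haplotypes_to_sequences(distinct_set, markers)
                seqs = seqs[::2]  # one per distinct haplotype
                if len(seqs) >= 3:
                    dm = distance_matrix(
                        seqs, labels=labels,
                        gamma_alpha=params.get("gamma_alpha", 1.0),
                    )
                    tree = nj_tree(dm)
                    newick = tree.newick()
                    ppio.write_newick(
                        os.path.join(out_dir, "haplotypes.nwk"), newick
                    )
                    report["results"]["phylo"] = {
                        "n_taxa": len(labels),
                        "newick": newick,
                        "n_clamped_edges": len(tree.clamped_edges),
                    }
                    report["stages"]["phylo"] = "ok"
                else:
                    report["stages"]["phylo"] = "skipped: <3 distinct haplotypes"
            except Exception as exc:
                logger.exception("phylo stage failed")
                report["stages"]["phylo"] = f"failed: {exc}"
                failures.append("phylo")

    if "assoc" in stages:
        if not downstream_ok or gm.phenotype is None:
            report["stages"]["assoc"] = "skipped: needs phase + phenotypes"
        else:
            try:
                params = config.get("assoc", {})
                pattern = params.get("pattern")
                if pattern is None:
                    # default scan: most frequent phased haplotype at the
                    # first marker as a carrier pattern (demo behaviour)
                    from collections import Counter as _C

                    top_allele = _C(haps.column(0)).most_common(1)[0][0]
                    pattern = {haps.marker_ids[0]: top_allele}
                table = carrier_table(
                    haps, pattern, gm.phenotype,
                    level=CountLevel(params.get("level", "subject")),
                )
                res = associate(table)
                report["stages"]["assoc"] = "ok"
                report["results"]["assoc"] = {
                    "pattern": {str(k): str(v) for k, v in pattern.items()},
                    "table": [table.a, table.b, table.c, table.d],
                    "level": table.level.value,
                    "p_two_sided": res.p_two_sided,
                    "odds_ratio": res.odds_ratio,
                    "ci95": list(res.ci95),
                    "correction_applied": res.correction_applied,
                }
            except Exception as exc:
                logger.exception("assoc stage failed")
                report["stages"]["assoc"] = f"failed: {exc}"
                failures.append("assoc")

    report["failed_stages"] = failures
    ppio.write_report(
        os.path.join(out_dir, "report.json"), report, seed=seed, config=config
    )
    return report
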