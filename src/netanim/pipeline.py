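"""End-to-end orchestration of the analysis stages.

Stage order: differential expression -> responsive-gene selection ->
network assembly -> layered layout -> pattern classification -> frame
rendering/animation -> (optional) promoter motif enrichment.  Every
stage's output is written to the run directory and is usable standalone;
a provenance manifest (input checksums, parameters, comparisons) makes a
run reproducible given its seed.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .animate import FrameStyle, assemble_animation, render_frame
from .core import Parameters, canonical_comparisons
from .diffexpr import fold_change_table, select_responsive, two_way_anova, write_fold_change_table
from .io import (
    file_checksum,
    read_comparisons,
    read_design,
    read_expression_matrix,
    read_interactions,
    read_localization,
    write_network,
)
from .layout import LayerScheme, layered_layout
from .motifs import extract_upstream, overrepresentation, read_meme_motifs
from .network import coexpression_edges, expression_profiles, merge_network, ppi_subnetwork
from .patterns import classify_all

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _parameters_from_config(config: dict) -> Parameters:
    keys = ("fc_threshold", "p_threshold", "corr_cutoff", "corr_mode",
            "upstream_length", "color_saturation", "seed")
    return Parameters(**{k: config[k] for k in keys if k in config})


def write_manifest(out_dir: Path, config: dict, params: Parameters, specs, inputs: dict) -> Path:
    manifest = {
        "tool": "netanim",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": {
            "fc_threshold": params.fc_threshold,
            "p_threshold": params.p_threshold,
            "corr_cutoff": params.corr_cutoff,
            "corr_mode": params.corr_mode,
            "upstream_length": params.upstream_length,
            "color_saturation": params.color_saturation,
            "seed": params.seed,
        },
        "comparisons": [
            {
                "id": s.id, "numerator": s.numerator, "denominator": s.denominator,
                "perturbed_factor": s.perturbed_factor, "order_index": s.order_index,
            }
            for s in specs
        ],
        "inputs": {
            key: {"path": str(path), "sha256": file_checksum(path)}
            for key, path in inputs.items()
            if path is not None and Path(path).exists()
        },
        "config": {k: v for k, v in config.items() if not isinstance(v, (dict, list))},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return path


def run_pipeline(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Run every stage on the inputs named in ``config``.

    Required config keys: ``expression``, ``design``, ``interactions``,
    ``localization``.  Optional: ``comparisons`` (defaults to the
    canonical four), ``promoters_fg``/``promoters_bg``/``motifs`` for the
    enrichment stage, ``anova_gate`` to additionally require an ANOVA
    effect p below threshold, plus any :class:`Parameters` field.

    On a stage error, previously written outputs are kept and a
    ``.partial`` marker names the failed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("expression", "design", "interactions", "localization"):
        if key not in config:
            raise KeyError(f"config missing required key: {key!r}")
    params = _parameters_from_config(config)

    marker = out / ".partial"
    stage = "read inputs"
    outputs: dict[str, Path] = {}
    try:
        marker.write_text(stage)
        expr = read_expression_matrix(config["expression"], linear_input=config.get("linear_input", False))
        design = read_design(config["design"], expr)
        specs = (
            read_comparisons(config["comparisons"])
            if config.get("comparisons")
            else canonical_comparisons()
        )

        stage = "diffexpr"
        marker.write_text(stage)
        fc = fold_change_table(expr, design, specs, params)
        outputs["fold_changes"] = out / "fold_changes.tsv"
        write_fold_change_table(fc, outputs["fold_changes"])
        anova = None
        if config.get("anova_gate", False):
            anova = two_way_anova(expr, design)
            outputs["anova"] = out / "anova.tsv"
            anova.rename_axis("gene").to_csv(outputs["anova"], sep="\t")

        stage = "select"
        marker.write_text(stage)
        responsive = select_responsive(fc, params, anova=anova)
        outputs["responsive_genes"] = out / "responsive_genes.txt"
        outputs["responsive_genes"].write_text("\n".join(sorted(responsive)) + "\n")
        log.info("%d responsive gene(s)", len(responsive))

        stage = "network"
        marker.write_text(stage)
        interactions = read_interactions(config["interactions"])
        annotation = read_localization(config["localization"])
        ppi = (
            ppi_subnetwork(responsive, interactions, config.get("include_neighbors", False))
            if responsive
            else []
        )
        profiles = expression_profiles(
            expr, genes=responsive, fc=fc, mode=config.get("profile_mode", "samples")
        )
        coexpr = coexpression_edges(profiles, params) if len(profiles) >= 2 else []
        network = merge_network(ppi, coexpr, annotation, fc, genes=responsive)
        outputs["network"] = out / "network.graphml"
        write_network(network, outputs["network"], "graphml")

        stage = "layout"
        marker.write_text(stage)
        scheme = LayerScheme()
        coords = layered_layout(network, annotation, scheme, seed=params.seed)
        outputs["layout"] = out / "layout.tsv"
        coords.write_tsv(outputs["layout"])

        stage = "classify"
        marker.write_text(stage)
        calls = classify_all(fc, specs, genes=sorted(responsive))
        outputs["patterns"] = out / "patterns.tsv"
        calls.to_csv(outputs["patterns"], sep="\t", index=False)

        stage = "animate"
        marker.write_text(stage)
        style = FrameStyle(saturation=params.color_saturation)
        ordered = sorted(specs, key=lambda s: s.order_index)
        frames = []
        for spec in ordered:
            sub = fc.loc[fc["comparison_id"] == spec.id]
            log2fc = dict(zip(sub["gene"], sub["log2fc"]))
            frames.append(
                render_frame(network, coords, log2fc, f"{spec.id}: {spec.numerator} vs {spec.denominator}", style)
            )
        if frames:
            anim = assemble_animation(
                frames, out / "animation",
                frame_duration_ms=config.get("frame_duration_ms", 1000),
                labels=[s.id for s in ordered],
            )
            outputs["animation"] = anim["gif"]
            outputs["flipbook"] = anim["html"]

        if config.get("promoters_fg") and config.get("promoters_bg") and config.get("motifs"):
            stage = "motifs"
            marker.write_text(stage)
            from Bio import SeqIO

            fg = {r.id: str(r.seq) for r in SeqIO.parse(str(config["promoters_fg"]), "fasta")}
            bg = {r.id: str(r.seq) for r in SeqIO.parse(str(config["promoters_bg"]), "fasta")}
            motif_list = read_meme_motifs(config["motifs"])
            enrichment = overrepresentation(fg, bg, motif_list)
            outputs["enrichment"] = out / "enrichment.tsv"
            enrichment.to_csv(outputs["enrichment"], sep="\t", index=False)

        stage = "manifest"
        outputs["manifest"] = write_manifest(
            out, config, params, specs,
            {k: config.get(k) for k in ("expression", "design", "interactions",
                                        "localization", "comparisons", "promoters_fg",
                                        "promoters_bg", "motifs")},
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    marker.unlink(missing_ok=True)
    return outputs
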