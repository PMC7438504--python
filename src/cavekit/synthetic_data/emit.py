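"""Materialise a simulated trajectory as files consumable by the pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..mutation_analysis.io import write_annotation_gff3, write_fasta
from .evolve import CaveTrajectory
from .assays import simulate_sequencing


def emit_outputs(trajectory: CaveTrajectory, outdir) -> dict:
    """Write reference FASTA, GFF3, per-round VCFs (wild-type background
    included in every sample plus a background-only negative control), and
    ground-truth TSVs.  Returns a manifest-ready dict of output paths.

    Sequencing noise is seeded from the trajectory seed, so identical
    trajectories yield byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = trajectory.config
    rng = np.random.default_rng(trajectory.seed + 10_000)

    fasta = outdir / "reference.fasta"
    write_fasta(fasta, trajectory.annotation.reference_id or "simref", trajectory.reference)
    gff = outdir / "genes.gff3"
    write_annotation_gff3(trajectory.annotation, gff)

    ref_id = trajectory.annotation.reference_id or "simref"
    ref_len = len(trajectory.reference)

    wt_vcf = outdir / "wildtype.vcf"
    simulate_sequencing(
        trajectory.background,
        depth=cfg.depth,
        error_rate=cfg.error_rate,
        seed=rng,
        sample="wildtype",
        reference_id=ref_id,
        vcf_path=str(wt_vcf),
        reference_length=ref_len,
    )

    vcfs = []
    for rec in trajectory.rounds[1:]:
        observed = dict(trajectory.background)
        for key, f in rec.allele_frequencies.items():
            observed[key] = min(1.0, f + observed.get(key, 0.0))
        path = outdir / f"round_{rec.round_index:02d}.vcf"
        simulate_sequencing(
            observed,
            depth=cfg.depth,
            error_rate=cfg.error_rate,
            seed=rng,
            sample=f"round_{rec.round_index:02d}",
            reference_id=ref_id,
            vcf_path=str(path),
            reference_length=ref_len,
        )
        vcfs.append(str(path))
    trajectory.vcf_paths = vcfs

    truth_rows = []
    for rec in trajectory.rounds:
        for (pos, ref, alt), f in sorted(rec.allele_frequencies.items()):
            truth_rows.append((rec.round_index, pos, ref, alt, f))
    pd.DataFrame(
        truth_rows, columns=["round", "pos", "ref", "alt", "true_freq"]
    ).to_csv(outdir / "true_frequencies.tsv", sep="\t", index=False)

    pd.DataFrame(
        {
            "round": [r.round_index for r in trajectory.rounds],
            "selection_temperature_c": [
                r.selection_temperature_c for r in trajectory.rounds
            ],
            "realized_selection_survival": [
                r.realized_survival for r in trajectory.rounds
            ],
            "assay_survival": [r.assay_survival for r in trajectory.rounds],
            "assay_survival_measured": [
                r.assay_survival_measured for r in trajectory.rounds
            ],
            "n_genotypes": [r.n_genotypes for r in trajectory.rounds],
        }
    ).to_csv(outdir / "survival.tsv", sep="\t", index=False)

    designated = {
        "stabilizing": [list(k) for k in trajectory.stabilizing_keys],
        "neutral_markers": [list(k) for k in trajectory.neutral_keys],
        "background": {f"{p}:{r}>{a}": f for (p, r, a), f in sorted(trajectory.background.items())},
        "seed": trajectory.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(designated, indent=2))

    return {
        "reference_fasta": str(fasta),
        "annotation_gff3": str(gff),
        "wildtype_vcf": str(wt_vcf),
        "round_vcfs": vcfs,
        "true_frequencies_tsv": str(outdir / "true_frequencies.tsv"),
        "survival_tsv": str(outdir / "survival.tsv"),
        "ground_truth_json": str(outdir / "ground_truth.json"),
    }
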