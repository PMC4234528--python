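"""Validation experiments on synthetic data.

Two standard checks of the whole pipeline, used by the test suite and the
reproduction script:

* ``recovery_run`` — can the pipeline recover planted OP classes and the
  functional terms coupled to them?  One default-sized dataset
  (3 classes x 40 segments x 20 kb in one GC bin, planting 5/kb,
  coupling beta = 0.8) per seed.
* ``null_calibration`` — with coupling beta = 0 the real OP groups carry
  no functional signal, so the real-vs-random Fisher comparison should be
  significant no more often than its nominal level.  Runs many reduced
  replicates (2 classes x 20 segments x 5 kb) and reports the fraction
  with p < alpha.  The reduced replicates use a higher gene density
  (2 genes per segment) so that the enrichment machinery is actually
  exercised under the null.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from compspec.pipeline import RunConfig, run_pipeline
from compspec.synthetic import SyntheticSpec, evaluate_recovery, generate_synthetic_dataset

#: Reduced study conditions for the null-calibration replicates.
NULL_SPEC_KWARGS = dict(
    classes=("op1", "op2"),
    n_segments_per_class=20,
    segment_len=5_000,
    n_chromosomes=2,
    coupling_beta=0.0,
    gene_density=2.0,
)


def _run_config(spec: SyntheticSpec, fasta, bed, terms, outdir,
                min_group_size: int, seed: int) -> RunConfig:
    return RunConfig(
        fasta=str(fasta),
        annotation=str(bed),
        term_map=str(terms),
        outdir=str(outdir),
        window_len=spec.segment_len,
        n_groups=len(spec.classes),
        min_group_size=min_group_size,
        random_seed=seed + 1_000_003,
    )


def recovery_run(seed: int, workdir: str | Path, spec: SyntheticSpec | None = None) -> dict:
    """Generate one planted dataset, run the full pipeline and score it.

    Returns the adjusted Rand index of the recovered OP groups against the
    planted classes, the set of linked terms flagged at adjusted
    p <= 0.05, and the real-vs-random Fisher p of the run.
    """
    workdir = Path(workdir)
    spec = spec if spec is not None else SyntheticSpec(seed=seed)
    fasta, bed, terms, truth = generate_synthetic_dataset(spec, workdir / "data")
    cfg = _run_config(spec, fasta, bed, terms, workdir / "run",
                      min_group_size=min(20, spec.n_segments_per_class // 2), seed=seed)
    manifest = run_pipeline(cfg)

    groups = pd.read_csv(cfg.out / "groups.tsv", sep="\t")
    predicted = dict(zip(groups.segment_id, groups.group_id))
    recovery = evaluate_recovery(predicted, truth.segment_to_class)

    enr = pd.read_csv(cfg.out / "enrichment.tsv", sep="\t")
    flagged = set(enr.loc[enr.p_adj <= 0.05, "term_id"])
    linked = set(truth.class_to_term.values())
    return {
        "seed": seed,
        "ari": recovery["ari"],
        "linked_terms": sorted(linked),
        "linked_terms_flagged": sorted(linked & flagged),
        "all_linked_flagged": linked <= flagged,
        "fisher_p": manifest["summary"]["fisher_p_two_tailed"],
    }


def null_calibration(
    n_replicates: int, seed: int, workdir: str | Path, alpha: float = 0.05
) -> dict:
    """Fraction of beta = 0 replicates whose real-vs-random Fisher
    comparison reaches p < alpha.  A calibrated pipeline keeps this at or
    below the nominal level."""
    workdir = Path(workdir)
    p_values = []
    for i in range(n_replicates):
        rep_seed = seed + 7919 * (i + 1)
        spec = SyntheticSpec(seed=rep_seed, **NULL_SPEC_KWARGS)
        rep_dir = workdir / f"rep{i:03d}"
        fasta, bed, terms, _ = generate_synthetic_dataset(spec, rep_dir / "data")
        cfg = _run_config(spec, fasta, bed, terms, rep_dir / "run",
                          min_group_size=5, seed=rep_seed)
        manifest = run_pipeline(cfg)
        p_values.append(manifest["summary"]["fisher_p_two_tailed"])
    n_sig = sum(p < alpha for p in p_values)
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "n_significant": n_sig,
        "fraction_significant": n_sig / n_replicates,
    }
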