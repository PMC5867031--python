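"""Reference simulation scenarios used for validation.

Three standard study conditions, mirroring the editing regimes observed
in the bread-wheat lines:

* :func:`recovery_scenario` — a 45-gene family (2% paralog divergence,
  40% pseudogenes) with 35 genes edited at 75% NHEJ, Q30 sequencing
  error, 50k reads per sample: the parameter-recovery condition of a
  high-efficiency line.  Insertions (19% of edits) are vector-derived:
  with score-based parent assignment, large insertions copied from the
  identical tandem epitope region of another family member can bridge
  the repeat-number length classes and make parentage ambiguous, so the
  recovery condition stays in the identifiable regime (see the methods
  note).
* :func:`null_scenario` — the same family, nothing edited, Q30 errors:
  the pipeline must report NHEJ = 0 and recover all 45 genes.
* :func:`spectrum_scenario` — deletion-only editing of every allele of a
  large pool, unbiased size weights, noiseless reads: used to check that
  the recovered deletion-size histogram follows the configured weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

from famedit.pipeline import PipelineParams, PipelineResult, run_analysis
from famedit.synthetic import (
    Allele,
    EditProfile,
    FamilyConfig,
    SampleReads,
    SyntheticFamily,
    TruthTable,
    apply_edits,
    default_vector,
    generate_family,
    simulate_reads,
)

__all__ = [
    "ScenarioRun",
    "recovery_scenario",
    "null_scenario",
    "spectrum_scenario",
]


@dataclass
class ScenarioRun:
    family: SyntheticFamily
    truth: TruthTable
    wt_reads: SampleReads
    mut_reads: SampleReads
    result: PipelineResult

    @property
    def spectrum(self):
        return self.result.spectra[self.mut_reads.sample_id]


def _simulate_and_run(
    family: SyntheticFamily,
    wt_pool,
    wt_truth,
    mut_pool,
    mut_truth,
    depth: int,
    quality: Optional[int],
    seed: int,
    params: PipelineParams,
) -> ScenarioRun:
    wt = simulate_reads(wt_pool, depth, quality, rng_seed=seed + 3, sample_id="WT1", truth=wt_truth)
    mut = simulate_reads(mut_pool, depth, quality, rng_seed=seed + 4, sample_id="MUT1", truth=mut_truth)
    result = run_analysis(
        {"WT1": wt.pairs},
        {"MUT1": mut.pairs},
        family.config.guide,
        vectors=[default_vector()],
        params=params,
    )
    return ScenarioRun(family, mut_truth, wt, mut, result)


def recovery_scenario(seed: int = 1, depth: int = 50_000) -> ScenarioRun:
    """High-efficiency editing: 35/45 genes at 75% NHEJ, Q30 errors."""
    cfg = FamilyConfig(
        n_genes=45, snp_rate=0.02, pseudogene_fraction=0.4, rng_seed=seed
    )
    family = generate_family(cfg)
    profile = EditProfile(
        nhej_fraction=0.75,
        insertion_fraction=0.19,
        insertion_origin_mix=(1.0, 0.0, 0.0),
    )
    wt_pool, wt_truth = apply_edits(
        family, cfg.guide, EditProfile(nhej_fraction=0.0), rng_seed=seed + 1
    )
    mut_pool, mut_truth = apply_edits(
        family, cfg.guide, profile, rng_seed=seed + 2, target_genes=35
    )
    return _simulate_and_run(
        family, wt_pool, wt_truth, mut_pool, mut_truth,
        depth, 30, seed, PipelineParams(),
    )


def null_scenario(seed: int = 1, depth: int = 2_000) -> ScenarioRun:
    """No editing, Q30 substitution errors only."""
    cfg = FamilyConfig(
        n_genes=45, snp_rate=0.02, pseudogene_fraction=0.4, rng_seed=seed
    )
    family = generate_family(cfg)
    null = EditProfile(nhej_fraction=0.0)
    wt_pool, wt_truth = apply_edits(family, cfg.guide, null, rng_seed=seed + 1)
    mut_pool, mut_truth = apply_edits(family, cfg.guide, null, rng_seed=seed + 2)
    return _simulate_and_run(
        family, wt_pool, wt_truth, mut_pool, mut_truth,
        depth, 30, seed, PipelineParams(),
    )


def spectrum_scenario(
    seed: int = 1,
    depth: int = 50_000,
    n_genes: int = 45,
    alleles_per_gene: int = 24,
) -> ScenarioRun:
    """Deletion-only editing of every allele; noiseless reads.

    All alleles are edited with unbiased default deletion weights
    (``mmej_bias=1``), so the true deletion-size distribution is the
    normalised weight table.  The representation threshold is lowered to
    0.05% because each of the ~1000 distinct mutant alleles holds only
    ~0.1% of the reads in this deep-spectrum condition.
    """
    cfg = FamilyConfig(
        n_genes=n_genes, snp_rate=0.02, pseudogene_fraction=0.4, rng_seed=seed
    )
    family = generate_family(cfg)
    profile = EditProfile(nhej_fraction=1.0, insertion_fraction=0.0, mmej_bias=1.0)
    wt_pool, wt_truth = apply_edits(
        family, cfg.guide, EditProfile(nhej_fraction=0.0), rng_seed=seed + 1
    )
    mut_pool, mut_truth = apply_edits(
        family, cfg.guide, profile, rng_seed=seed + 2,
        alleles_per_gene=alleles_per_gene,
    )
    params = PipelineParams(min_frequency=0.0005)
    return _simulate_and_run(
        family, wt_pool, wt_truth, mut_pool, mut_truth,
        depth, None, seed, params,
    )


def spectrum_chi2(run: ScenarioRun) -> Dict[str, float]:
    """Goodness of fit of the recovered deletion-size histogram to the
    configured weights.

    The read-weighted histogram is rescaled to allele equivalents
    (reads per true allele) and compared to the expected multinomial by
    a chi-square test, pooling sizes until every expected bin count is
    at least 5.  Returns {"chi2": ..., "p": ..., "n": ...}.
    """
    import numpy as np
    from scipy import stats

    profile_weights = EditProfile().deletion_weights()  # default table
    spec = run.spectrum
    hist = spec.deletion_hist
    n_alleles = sum(1 for r in run.truth if r.edit_type == "deletion")
    total_reads = sum(hist.values())
    mu = total_reads / n_alleles
    sizes = sorted(profile_weights)
    w = np.array([profile_weights[s] for s in sizes])
    p = w / w.sum()
    obs = np.array([hist.get(s, 0) / mu for s in sizes])
    # pool the tail so every expected count is >= 5
    exp = p * n_alleles
    obs_b, exp_b = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs_b.append(acc_o)
            exp_b.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        obs_b[-1] += acc_o
        exp_b[-1] += acc_e
    obs_b = np.array(obs_b)
    exp_b = np.array(exp_b) * obs_b.sum() / sum(exp_b)
    chi2, pval = stats.chisquare(obs_b, exp_b)
    return {"chi2": float(chi2), "p": float(pval), "n": float(n_alleles)}
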