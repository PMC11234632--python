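"""End-to-end single-trait analysis: GWAS -> weights -> weighted GBLUP.

The GWAS-assisted prediction workflow is (1) an association scan on the
training cows producing per-SNP likelihood ratios, (2) moving-average
smoothing of those ratios, (3) conversion to posterior probabilities
given the prior pi, (4) a weighted genomic relationship matrix with those
posteriors as SNP weights, and (5) GBLUP prediction with the weighted
matrix.  This module wires the steps together for one trait and a set of
prediction modes so the command-line tool, the test-bench simulations and
interactive use all run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bayesgc as bayesgc_mod
from .datamodel import (
    GenotypeSet,
    TraitObservations,
    VarianceComponents,
    center_genotypes,
    compute_observation_weights,
    weighted_allele_freq,
)
from .evaluate import EvaluationReport, evaluate_methods
from .grm import GRMatrix, build_grm
from .gwas import GwasScanResult, emmax_scan
from .mixed_model import GblupFit, MixedModelSpec, reml_estimate
from .weights import make_weights


@dataclass
class SingleTraitResult:
    trait: str
    varcomp_used: tuple[float, float]
    reml: object | None
    scan: GwasScanResult | None
    fits: dict[str, GblupFit | object]
    gebv_validation: dict[str, np.ndarray]
    evaluation: EvaluationReport | None
    G_u: GRMatrix
    train_ids: list[str] = field(default_factory=list)
    validation_ids: list[str] = field(default_factory=list)


def run_single_trait(
    genotypes: GenotypeSet,
    observations: TraitObservations,
    trait: str,
    vc: VarianceComponents,
    modes: tuple[str, ...] = ("gblup", "gwablup"),
    window: int = 5,
    pi: float = 0.001,
    p_threshold: float = 1e-7,
    min_peak_gap_bp: int = 1_000_000,
    top_weight: float = 1000.0,
    prediction_varcomp: tuple[float, float] | None = None,
    reestimate: bool = False,
    evaluate: bool = True,
    bayesgc_config: "bayesgc_mod.BayesGCConfig | None" = None,
    bootstrap_B: int = 10_000,
    seed: int = 0,
) -> SingleTraitResult:
    """Run the full workflow for one trait and several prediction modes.

    ``vc`` supplies the lactation-model ratios for observation weights; the
    (sigma2_g, sigma2_e) pair used in prediction is REML-estimated with the
    unweighted matrix unless ``prediction_varcomp`` is given.  Weighted-G
    analyses reuse those estimates unless ``reestimate`` is set.  Modes:
    ``gblup``, ``topsnps``, ``gwablup``, ``bayesgc``.
    """
    observations.check_against(genotypes)
    w = compute_observation_weights(observations, vc)
    train_ids = observations.ids_for("train")
    validation_ids = observations.ids_for("validation")
    roles = dict(zip(observations.sample_ids, observations.table["role"]))
    y_train = observations.table.set_index("sample_id").loc[train_ids, trait]
    y_train = y_train.to_numpy(dtype=float)
    w_train = w.as_series().reindex(train_ids).to_numpy()

    p = weighted_allele_freq(genotypes, w, train_ids)
    X = center_genotypes(genotypes, p, w, train_ids)
    G_u = build_grm(X)
    spec = MixedModelSpec(
        G=G_u, y=y_train, train_ids=train_ids,
        validation_ids=validation_ids, R_diag=1.0 / w_train,
    )
    reml = None
    if prediction_varcomp is None:
        reml = reml_estimate(spec)
        varcomp = (reml.sigma2_g, reml.sigma2_e)
    else:
        varcomp = tuple(prediction_varcomp)

    needs_scan = any(m in ("gwablup", "topsnps") for m in modes)
    scan = None
    if needs_scan:
        scan = emmax_scan(
            y_train, X, G_u, varcomp, train_ids,
            R_diag=1.0 / w_train, trait=trait, spec=spec,
        )

    from .mixed_model import gblup_solve  # local to avoid cycle at import

    fits: dict[str, object] = {}
    gebv_val: dict[str, np.ndarray] = {}
    for mode in modes:
        if mode == "bayesgc":
            cfg = bayesgc_config or bayesgc_mod.BayesGCConfig(
                cycles=2000, burnin=500, chains=2, seed=seed
            )
            fit = bayesgc_mod.bayesgc_fit(
                y_train, X, G_u, varcomp, cfg, train_ids,
                validation_ids=validation_ids, R_diag=1.0 / w_train,
            )
            fits[mode] = fit
            gebv_val[mode] = fit.gebv.reindex(validation_ids).to_numpy()
            continue
        if mode == "gblup":
            G_mode, vc_mode = G_u, varcomp
        else:
            D = make_weights(
                mode, scan, window=window, pi=pi, p_threshold=p_threshold,
                min_peak_gap_bp=min_peak_gap_bp, top_weight=top_weight,
            )
            G_mode = build_grm(X, D)
            if reestimate:
                spec_d = MixedModelSpec(
                    G=G_mode, y=y_train, train_ids=train_ids,
                    validation_ids=validation_ids, R_diag=1.0 / w_train,
                )
                re_est = reml_estimate(spec_d)
                vc_mode = (re_est.sigma2_g, re_est.sigma2_e)
            else:
                vc_mode = varcomp
        spec_mode = MixedModelSpec(
            G=G_mode, y=y_train, train_ids=train_ids,
            validation_ids=validation_ids, R_diag=1.0 / w_train,
        )
        fit = gblup_solve(spec_mode, vc_mode)
        fits[mode] = fit
        gebv_val[mode] = fit.gebv_for(validation_ids)

    report = None
    if evaluate and validation_ids:
        y_val = observations.table.set_index("sample_id").loc[
            validation_ids, trait
        ].to_numpy(dtype=float)
        reference = "gblup" if "gblup" in gebv_val else list(gebv_val)[0]
        report = evaluate_methods(
            y_val, gebv_val, reference=reference, trait=trait,
            B=bootstrap_B, seed=seed,
        )
    return SingleTraitResult(
        trait=trait,
        varcomp_used=varcomp,
        reml=reml,
        scan=scan,
        fits=fits,
        gebv_validation=gebv_val,
        evaluation=report,
        G_u=G_u,
        train_ids=train_ids,
        validation_ids=validation_ids,
    )


@dataclass
class MultiTraitResult:
    transform: object
    combined_scan: GwasScanResult | None
    gebv: dict[str, "np.ndarray"]  # mode -> all-animals x traits array
    ids: list[str]
    trait_names: list[str]
    validation_ids: list[str]


def run_multitrait(
    genotypes: GenotypeSet,
    observations: TraitObservations,
    cov,
    vc: VarianceComponents,
    modes: tuple[str, ...] = ("mtgblup", "mtgwablup"),
    window: int = 5,
    pi: float = 0.001,
    p_threshold: float = 1e-7,
    min_peak_gap_bp: int = 1_000_000,
    top_weight: float = 1000.0,
) -> MultiTraitResult:
    """Canonical-transformation multitrait prediction.

    Traits are rotated into independent canonical traits (unit
    environmental variance), each analysed by single-trait GBLUP with the
    canonical genetic variance from ``cov``.  GWAS signals of the canonical
    traits are summed per SNP into one combined likelihood ratio, giving a
    single shared weight vector (the related-traits assumption); canonical
    GEBV are back-transformed to the original traits.  ``vc`` supplies the
    lactation-model ratios for the shared observation weights.
    """
    from .multitrait import (
        back_transform,
        canonical_transform,
        combine_canonical_lr,
        to_canonical,
    )
    from .mixed_model import gblup_solve

    observations.check_against(genotypes)
    traits = list(cov.trait_names)
    w = compute_observation_weights(observations, vc)
    train_ids = observations.ids_for("train")
    validation_ids = observations.ids_for("validation")
    w_train = w.as_series().reindex(train_ids).to_numpy()
    p = weighted_allele_freq(genotypes, w, train_ids)
    X = center_genotypes(genotypes, p, w, train_ids)
    G_u = build_grm(X)

    transform = canonical_transform(cov)
    Y_train = observations.table.set_index("sample_id").loc[
        train_ids, traits
    ].to_numpy(dtype=float)
    Yc = to_canonical(Y_train, transform)
    canvars = transform.canonical_genetic_variances

    combined = None
    if any(m in ("mtgwablup", "mttopsnps") for m in modes):
        shared = MixedModelSpec(
            G=G_u, y=Yc[:, 0], train_ids=train_ids,
            validation_ids=validation_ids, R_diag=1.0 / w_train,
        )  # one spectral decomposition serves every canonical scan
        scans = [
            emmax_scan(
                Yc[:, t], X, G_u, (max(canvars[t], 1e-8), 1.0), train_ids,
                R_diag=1.0 / w_train, trait=f"canonical{t + 1}", spec=shared,
            )
            for t in range(len(traits))
        ]
        combined = combine_canonical_lr(scans)

    gebv_by_mode: dict[str, np.ndarray] = {}
    for mode in modes:
        if mode == "mtgblup":
            G_mode = G_u
        elif mode == "mtgwablup":
            D = make_weights(
                "gwablup", combined, window=window, pi=pi
            )
            G_mode = build_grm(X, D)
        elif mode == "mttopsnps":
            D = make_weights(
                "topsnps", combined, p_threshold=p_threshold,
                min_peak_gap_bp=min_peak_gap_bp, top_weight=top_weight,
            )
            G_mode = build_grm(X, D)
        else:
            raise ValueError(f"unknown multitrait mode {mode!r}")
        gebv_c = np.column_stack(
            [
                gblup_solve(
                    MixedModelSpec(
                        G=G_mode, y=Yc[:, t], train_ids=train_ids,
                        validation_ids=validation_ids,
                        R_diag=1.0 / w_train,
                    ),
                    (max(canvars[t], 1e-8), 1.0),
                ).gebv.to_numpy()
                for t in range(len(traits))
            ]
        )
        gebv_by_mode[mode] = back_transform(gebv_c, transform)
    return MultiTraitResult(
        transform=transform,
        combined_scan=combined,
        gebv=gebv_by_mode,
        ids=list(G_u.ids),
        trait_names=traits,
        validation_ids=validation_ids,
    )
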