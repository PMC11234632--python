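"""Published reference numbers for the Norwegian Red dairy-cattle traits.

Variance components for milk, fat and protein yield and log somatic cell
count (SCC) as used in the Norwegian Red national breeding-value
evaluation, together with the forward-validation summary statistics of a
standard GBLUP analysis of those traits (squared correlation between
validation-cow yield deviations and their genomic predictions, and the
mean reliability of the validation-cow yield deviations).  Milk-yield
variances are on a kg^2 x 10^3 scale; fat and protein on kg^2; SCC on the
log-cell-count scale.  These serve as worked-example inputs: the real
genotype/phenotype data (32,201 cows x 617,739 SNPs) are not distributed.
"""

from __future__ import annotations

from .datamodel import VarianceComponents

TRAITS = ["milk", "fat", "protein", "scc"]

#: national-evaluation variance components (genetic, permanent environment,
#: residual) per trait
VARIANCE_COMPONENTS: dict[str, VarianceComponents] = {
    "milk": VarianceComponents(sigma2_g=448.0, sigma2_pe=283.0, sigma2_e=735.0),
    "fat": VarianceComponents(sigma2_g=642.0, sigma2_pe=529.0, sigma2_e=1782.0),
    "protein": VarianceComponents(sigma2_g=362.0, sigma2_pe=347.0, sigma2_e=818.0),
    "scc": VarianceComponents(sigma2_g=0.152, sigma2_pe=0.199, sigma2_e=0.551),
}

#: forward-validation cor(y_v, g_hat_v)^2 of standard GBLUP per trait
GBLUP_COR2: dict[str, float] = {
    "milk": 0.209,
    "fat": 0.186,
    "protein": 0.196,
    "scc": 0.178,
}

#: mean reliability of the validation cows' yield deviations per trait
VALIDATION_YD_RELIABILITY: dict[str, float] = {
    "milk": 0.409,
    "fat": 0.316,
    "protein": 0.326,
    "scc": 0.246,
}


def gblup_actual_reliability(trait: str) -> float:
    """Actual GBLUP prediction reliability for a reference trait.

    The squared validation correlation understates the reliability of the
    genomic prediction because the validation phenotype (a yield deviation)
    is itself an imperfect measure of the genetic value; dividing by the
    mean YD reliability of the validation cows corrects for this.
    """
    return GBLUP_COR2[trait] / VALIDATION_YD_RELIABILITY[trait]
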