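"""Enzymatic and microglial clearance of Abeta, and APOE/sex risk factors.

Soluble monomer is degraded by proteases (neprilysin, insulin-degrading
enzyme) modelled as Hill kinetics whose capacity declines with age.
Insoluble assemblies (o, O, F, P) are cleared by microglia at a rate
mixing a high (functional) and a low (dysfunctional) phenotype:

    kg_i = mu(t) * [ fr(t) * Vi_high + (1 - fr(t)) * Vi_low ]

with mu the normalised microglia density (1 at homeostasis) and fr the
phenotype fraction (0.03 at homeostasis). Oligomers and protofibrils
share one rate; the plaque rate is 50% of it. APOE status multiplies
kg by (1 - alpha), alpha in [-0.02, 1]; outside the CNS monomers decay
at a constant 1.9e-4/s.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import PER_SECOND_TO_PER_HOUR, ParameterSet

__all__ = [
    "MicrogliaState",
    "ClearanceParams",
    "RiskProfile",
    "GENOTYPES",
    "microglial_clearance_rate",
    "microglia_density",
    "apply_apoe",
    "enzymatic_degradation_rate",
    "peripheral_degradation",
    "risk_profile_from_genotype",
    "phenotype_fraction",
]

GENOTYPES = ("e2/e2", "e2/e3", "e3/e3", "e2/e4", "e3/e4", "e4/e4")
SEXES = ("male", "female")

#: species subject to microglial clearance (monomers/dimers are not)
MICROGLIAL_SPECIES = ("o", "O", "F", "P")


class RiskValidationError(ValueError):
    pass


@dataclass(frozen=True)
class MicrogliaState:
    """Normalised density and phenotype fraction."""

    mu: float = 1.0
    fr: float = 0.03

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("microglia density mu must be >= 0")
        if not 0.0 <= self.fr <= 1.0:
            raise ValueError("phenotype fraction fr must lie in [0, 1]")


@dataclass(frozen=True)
class ClearanceParams:
    Vmax0: float                  # nM/h enzymatic capacity at young age
    Km: float                     # nM half-saturation
    hill_n: float
    vmax_decline_per_year: float
    vmax_decline_onset_age: float
    kperiph_per_s: float
    V_oOF_high: float             # 1/h, shared by o, O, F
    V_oOF_low: float
    plaque_rate_ratio: float      # V_P / V_oOF, 0.5 by default
    fr0: float
    mu0: float
    fr_pmid: float
    fr_hill: float
    mu_pmid: float
    mu_hill: float
    k_mac_pv: float
    load_factor: float

    def __post_init__(self):
        if self.Km <= 0:
            raise ValueError("Km must be positive")
        if not 0.0 <= self.V_oOF_low <= self.V_oOF_high:
            raise ValueError("require V_high >= V_low >= 0")

    @classmethod
    def from_parameter_set(cls, params: ParameterSet) -> "ClearanceParams":
        c = params.section("clearance")
        return cls(
            Vmax0=float(c["Vmax0"]), Km=float(c["Km"]), hill_n=float(c["hill_n"]),
            vmax_decline_per_year=float(c["vmax_decline_per_year"]),
            vmax_decline_onset_age=float(c["vmax_decline_onset_age"]),
            kperiph_per_s=float(c["kperiph_per_s"]),
            V_oOF_high=float(c["V_oOF_high"]), V_oOF_low=float(c["V_oOF_low"]),
            plaque_rate_ratio=float(c["plaque_rate_ratio"]),
            fr0=float(c["fr0"]), mu0=float(c["mu0"]),
            fr_pmid=float(c["fr_pmid"]), fr_hill=float(c["fr_hill"]),
            mu_pmid=float(c["mu_pmid"]), mu_hill=float(c["mu_hill"]),
            k_mac_pv=float(c["k_mac_pv"]), load_factor=float(c["load_factor"]),
        )

    @property
    def kperiph(self) -> float:
        """Peripheral monomer degradation constant in 1/h."""
        return self.kperiph_per_s * PER_SECOND_TO_PER_HOUR

    def species_rates(self, level: str) -> dict[str, float]:
        """High or low microglial rate per insoluble species (1/h)."""
        if level not in ("high", "low"):
            raise ValueError("level must be 'high' or 'low'")
        v = self.V_oOF_high if level == "high" else self.V_oOF_low
        return {"o": v, "O": v, "F": v, "P": self.plaque_rate_ratio * v}


@dataclass(frozen=True)
class RiskProfile:
    """APOE genotype and sex mapped to clearance modifiers."""

    apoe_genotype: str
    sex: str
    alpha: float
    risk_multiplier: float

    def __post_init__(self):
        if self.apoe_genotype not in GENOTYPES:
            raise RiskValidationError(f"unknown genotype {self.apoe_genotype!r}")
        if self.sex not in SEXES:
            raise RiskValidationError(f"unknown sex {self.sex!r}")
        if not -0.02 <= self.alpha <= 1.0:
            raise RiskValidationError(
                f"alpha must lie in [-0.02, 1], got {self.alpha}"
            )

    @property
    def is_carrier(self) -> bool:
        return self.alpha != 0.0


def microglial_clearance_rate(
    species: str, mg: MicrogliaState, p: ClearanceParams
) -> float:
    """kg_i = mu * [fr * Vi_high + (1 - fr) * Vi_low] for i in {o, O, F, P}."""
    if species not in MICROGLIAL_SPECIES:
        raise ValueError(
            f"species {species!r} is not microglially cleared "
            f"(expected one of {MICROGLIAL_SPECIES})"
        )
    vh = p.species_rates("high")[species]
    vl = p.species_rates("low")[species]
    return mg.mu * (mg.fr * vh + (1.0 - mg.fr) * vl)


def apply_apoe(kg: float, profile: RiskProfile) -> float:
    """Scale a microglial clearance rate by the APOE factor (1 - alpha)."""
    if kg < 0:
        raise ValueError("clearance rate must be >= 0")
    return kg * (1.0 - profile.alpha)


def enzymatic_degradation_rate(M: float, age: float, p: ClearanceParams) -> float:
    """Hill-kinetics protease degradation of soluble monomer (nM/h).

    Vmax declines linearly with age beyond the onset age and is floored
    at zero, so the rate is non-increasing in age for every M.
    """
    if M < 0:
        raise ValueError("monomer concentration must be >= 0")
    if age < 0:
        raise ValueError("age must be >= 0")
    vmax = vmax_at_age(age, p)
    if M == 0.0:
        return 0.0
    Mn = M ** p.hill_n
    return vmax * Mn / (p.Km ** p.hill_n + Mn)


def vmax_at_age(age: float, p: ClearanceParams) -> float:
    decline = p.vmax_decline_per_year * max(0.0, age - p.vmax_decline_onset_age)
    return p.Vmax0 * max(0.0, 1.0 - decline)


def peripheral_degradation(M_compartment: float, p: ClearanceParams) -> float:
    """First-order loss (nM/h) of monomer outside the CNS."""
    return p.kperiph * M_compartment


def phenotype_fraction(plaque_burden: float, p: ClearanceParams) -> float:
    """Saturating rise of fr from fr0 toward 1 with total plaque burden.

    Models recruitment of the phagocytic phenotype as amyloid pathology
    accumulates: fr(0) = fr0 and fr -> 1 as the burden passes fr_pmid
    (Hill midpoint). This is the pluggable activation response; the
    default AD-prone trajectory instead pins fr at fr0 (activation
    fails) and expresses dysfunction through :func:`microglia_density`.
    """
    P = max(0.0, plaque_burden)
    x = P ** p.fr_hill
    return p.fr0 + (1.0 - p.fr0) * x / (x + p.fr_pmid ** p.fr_hill)


def microglia_density(plaque_burden: float, p: ClearanceParams) -> float:
    """Normalised microglia density mu as a function of plaque burden.

    mu = 1 at homeostasis and declines toward zero once the burden
    passes ``mu_pmid`` (Hill midpoint ``mu_hill``), modelling exhaustion
    and senescence of the clearing population in advanced pathology.
    Plaque can therefore accumulate orders of magnitude beyond the
    level a constant first-order microglial sink would allow.
    """
    P = max(0.0, plaque_burden)
    x = (P / p.mu_pmid) ** p.mu_hill
    return p.mu0 / (1.0 + x)


def risk_profile_from_genotype(
    genotype: str, sex: str, params: ParameterSet | None = None
) -> RiskProfile:
    """Look up alpha and the relative AD risk for a genotype/sex pair."""
    if params is None:
        params = ParameterSet.defaults()
    if genotype not in GENOTYPES:
        raise RiskValidationError(f"unknown genotype {genotype!r}")
    if sex not in SEXES:
        raise RiskValidationError(f"unknown sex {sex!r}")
    alpha = float(params.get(f"risk.alpha.{genotype}"))
    mult = float(params.get(f"risk.risk_multiplier.{genotype}.{sex}"))
    return RiskProfile(apoe_genotype=genotype, sex=sex, alpha=alpha,
                       risk_multiplier=mult)


def sex_clearance_factor(sex: str, params: ParameterSet) -> float:
    if sex not in SEXES:
        raise RiskValidationError(f"unknown sex {sex!r}")
    return float(params.get(f"risk.sex_clearance_factor.{sex}"))
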