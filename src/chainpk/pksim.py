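"""Synthetic pharmacokinetic data with the structure the chain framework assumes.

The real concentration measurements behind the Wuji pill compatibility study
are not public, so this module generates stand-in datasets with the same
layout and the statistical features that matter for chained multi-target
regression: composition-driven curves, a single absorption peak with lag and
first-order terminal decline, serially correlated targets, and multiplicative
assay noise.

The mechanistic core is a one-compartment oral-absorption model with lag:

    C(t) = (D / (V/F)) * ka / (ka - ke) * (exp(-ke*(t-tlag)) - exp(-ka*(t-tlag)))

for t > tlag and 0 before.  The compound dose D follows from the prescription:
amount of the source herb x the compound's mass fraction in that herb's
extract x a unit dose scale.  Compatibility (the other two herbs) perturbs
the absorption and elimination rates log-linearly, so the curve shape -- not
just its height -- depends on the full prescription.

A per-sample lognormal random effect on dose (biological replicate
variability) scales each whole curve up or down, which makes the nine time
points of one sample correlated beyond what the composition explains --
exactly the correlation a chained regressor can exploit.  Point-wise
multiplicative lognormal noise models assay error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import (
    DEFAULT_SIMULATION_LABELS,
    HERBS,
    ConcentrationDataset,
    DesignRow,
    DesignTable,
    TimeGrid,
    builtin_design,
    standard_time_grid,
)

logger = logging.getLogger(__name__)


class DegenerateParameterError(ValueError):
    """ka equals ke; the two-exponential form is singular there."""


@dataclass(frozen=True)
class CompoundInfo:
    """A marker compound, its source herb, and its mass fraction in the
    herb's dried extract."""

    name: str
    herb: str
    mass_fraction: float

    def __post_init__(self) -> None:
        if self.herb not in HERBS:
            raise ValueError(f"unknown herb {self.herb!r}")
        if not 0.0 < self.mass_fraction < 1.0:
            raise ValueError("mass_fraction must be in (0, 1)")


#: The five marker compounds and their measured extract mass fractions:
#: berberine and palmatine from coptis, evodiamine and rutecarpine from
#: evodia, paeoniflorin from peony.
COMPOUND_INFO: dict[str, CompoundInfo] = {
    "ber": CompoundInfo("ber", "coptis", 0.2303),
    "pal": CompoundInfo("pal", "coptis", 0.0552),
    "evo": CompoundInfo("evo", "evodia", 0.0038),
    "rut": CompoundInfo("rut", "evodia", 0.0048),
    "pae": CompoundInfo("pae", "peony", 0.1341),
}


@dataclass(frozen=True)
class PKParameters:
    """One-compartment oral model parameters.

    ka, ke in 1/min with ka > ke (absorption faster than elimination);
    V_F is the apparent volume of distribution over bioavailability;
    tlag the absorption delay in minutes; dose the administered amount.
    """

    ka: float = 0.05
    ke: float = 0.008
    V_F: float = 1.0
    tlag: float = 10.0
    dose: float = 1.0

    def __post_init__(self) -> None:
        if self.ka == self.ke:
            raise DegenerateParameterError("ka == ke is not supported")
        if not (self.ka > self.ke > 0):
            raise ValueError("require ka > ke > 0")
        if self.V_F <= 0:
            raise ValueError("V_F must be positive")
        if self.tlag < 0 or self.dose < 0:
            raise ValueError("tlag and dose must be non-negative")

    @property
    def tmax(self) -> float:
        """Time of the concentration peak: tlag + ln(ka/ke)/(ka-ke)."""
        return self.tlag + np.log(self.ka / self.ke) / (self.ka - self.ke)

    @property
    def auc_inf(self) -> float:
        """Total exposure integral: (dose / V_F) / ke."""
        return (self.dose / self.V_F) / self.ke


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise, parameterised to mean 1 at any CV."""

    cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def _lognormal_mean1(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def concentration_at(t, p: PKParameters) -> np.ndarray:
    """Noiseless concentration at time(s) ``t`` (minutes); zero up to tlag."""
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - p.tlag, 0.0)
    amp = (p.dose / p.V_F) * p.ka / (p.ka - p.ke)
    c = amp * (np.exp(-p.ke * dt) - np.exp(-p.ka * dt))
    return np.maximum(c, 0.0)


@dataclass(frozen=True)
class InteractionCoefficients:
    """Log-linear compatibility effects of the two non-source herbs.

    ``ka_coef[h]`` (resp. ``ke_coef[h]``) multiplies the amount of herb ``h``
    in the exponent perturbing ka (resp. ke):

        ka_eff = ka * exp( sum_h ka_coef[h] * amount_h )   (h != source herb)

    Defaults are modest positive absorption and negative elimination effects,
    so richer compatibilities absorb faster and clear slower.
    """

    ka_coef: tuple[float, float, float] = (0.20, 0.20, 0.20)
    ke_coef: tuple[float, float, float] = (-0.15, -0.15, -0.15)

    def coef(self, which: str, herb: str) -> float:
        idx = HERBS.index(herb)
        return (self.ka_coef if which == "ka" else self.ke_coef)[idx]


def pk_from_composition(
    row: DesignRow,
    compound: CompoundInfo,
    base: PKParameters | None = None,
    interaction: InteractionCoefficients | None = None,
    unit_dose: float = 1000.0,
) -> PKParameters:
    """Derive a sample's PK parameters from its prescription composition.

    Dose is linear in the source-herb amount; ka and ke are perturbed
    log-linearly by the amounts of the *other* two herbs.  If a perturbation
    would drive ka below ke, ka is clipped to 1.05 x ke with a warning.
    """
    base = base or PKParameters()
    interaction = interaction or InteractionCoefficients()
    dose = row.amount(compound.herb) * compound.mass_fraction * unit_dose
    others = [h for h in HERBS if h != compound.herb]
    ka = base.ka * np.exp(sum(interaction.coef("ka", h) * row.amount(h) for h in others))
    ke = base.ke * np.exp(sum(interaction.coef("ke", h) * row.amount(h) for h in others))
    if ka <= ke:
        logger.warning(
            "interaction drove ka (%.4g) <= ke (%.4g) for %s/%s; clipping ka",
            ka, ke, compound.name, row.label,
        )
        ka = 1.05 * ke
    return replace(base, ka=float(ka), ke=float(ke), dose=float(dose))


#: CV of the per-sample lognormal random effect on dose (replicate-level
#: biological variability shared across the sample's whole curve).
DEFAULT_LATENT_CV = 0.10


def simulate_dataset(
    design: DesignTable | None = None,
    compound: CompoundInfo | str = "ber",
    base: PKParameters | None = None,
    interaction: InteractionCoefficients | None = None,
    replicates: int = 3,
    noise: NoiseModel | None = None,
    grid: TimeGrid | None = None,
    latent_cv: float = DEFAULT_LATENT_CV,
    unit_dose: float = 1000.0,
) -> ConcentrationDataset:
    """Simulate one compound's dataset: |design| groups x ``replicates`` samples.

    With the default 12-prescription design and 3 replicates this yields the
    study-sized 36 samples.  Deterministic given the noise seed; ``cv=0`` and
    ``latent_cv=0`` reproduce the noiseless curves exactly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(compound, str):
        compound = COMPOUND_INFO[compound]
    design = design if design is not None else builtin_design().select(DEFAULT_SIMULATION_LABELS)
    grid = grid or standard_time_grid()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    times = grid.asarray()

    X_rows, Y_rows, groups = [], [], []
    for row in design.rows:
        p = pk_from_composition(row, compound, base, interaction, unit_dose)
        curve = concentration_at(times, p)
        for _ in range(replicates):
            scale = _lognormal_mean1(rng, latent_cv, size=None)
            eps = _lognormal_mean1(rng, noise.cv, size=len(times))
            X_rows.append(row.amounts())
            Y_rows.append(curve * scale * eps)
            groups.append(row.label)

    return ConcentrationDataset(
        compound=compound.name,
        X=np.array(X_rows),
        Y=np.array(Y_rows),
        grid=grid,
        group_ids=tuple(groups),
    )


def default_suite(seed: int = 0, **kwargs) -> dict[str, ConcentrationDataset]:
    """Simulate all five compounds under default study conditions.

    Each compound gets an independent noise stream derived from ``seed``."""
    suite = {}
    for i, name in enumerate(COMPOUND_INFO):
        suite[name] = simulate_dataset(
            compound=name, noise=NoiseModel(seed=seed * 10 + i), **kwargs
        )
    return suite
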