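"""Seeded synthetic CPD cohorts with group-conditional distributions.

No patient-level CPD cohort is publicly deposited for this problem, so the
simulator emulates one: each diagnosis group draws every CPD parameter from
a configurable marginal distribution.  Dispersion-type (SD-) parameters
default to lognormal marginals (strictly positive, right-skewed, as
instrument dispersion statistics tend to be); mean-type (MN-) parameters
default to normals truncated at zero.  Distribution parameters are given as
the desired mean and standard deviation on the natural scale.

``paper_like_config`` ships the study conditions used throughout the test
suite: the nine diagnosis groups at their real cohort sizes (1056 normal,
47 reactive, 62 AML, 30 APL, 54 ALL, 47 lymphoma, 28 CLL, 12 CML, 12 MDS;
1348 samples) with effect sizes tuned so that exactly the four published
screening parameters separate neoplastic from non-neoplastic samples with
AUC > 0.9, MN-AL2-NE separates neoplastic from reactive, and the subtype
parameters show the moderate (AUC ~ 0.7) one-vs-rest separations of the
published subtype discriminants.  Within-group correlations default to
independence; an optional single-factor correlation per cell type is
available to stress-test composite scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import DEFAULT_LABEL_SCHEME, Cohort, CPDRecord
from .parameters import canonical_parameters, parse_parameter

FAMILIES = ("normal", "lognormal")


@dataclass(frozen=True)
class Marginal:
    """One parameter's marginal: family plus natural-scale mean and SD."""

    family: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.sd <= 0:
            raise ValueError("scale must be > 0")
        if self.family == "lognormal" and self.mean <= 0:
            raise ValueError("lognormal mean must be > 0")


@dataclass
class GroupSpec:
    """Sampling specification for one diagnosis group.

    ``overrides`` maps canonical parameter names to marginals that replace
    the roster defaults for this group.  ``correlation`` optionally gives a
    single-factor within-cell-type correlation (rho per cell type).
    """

    label: str
    n: int
    overrides: dict[str, Marginal] = field(default_factory=dict)
    correlation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"group {self.label!r}: n must be >= 0")
        for cell, rho in self.correlation.items():
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"group {self.label!r}: rho for {cell} outside [0, 1)")


@dataclass
class SimulationConfig:
    """Full simulation recipe: groups, seed, and the parameter roster."""

    groups: list[GroupSpec]
    seed: int
    roster: list[str] = field(
        default_factory=lambda: [str(p) for p in canonical_parameters()]
    )
    defaults: dict[str, Marginal] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for name in self.roster:
            parse_parameter(name)  # validates the roster


def _default_marginal(name: str) -> Marginal:
    """Fallback marginal for a parameter not configured explicitly."""
    p = parse_parameter(name)
    if p.statistic == "SD":
        return Marginal("lognormal", 14.0, 3.0)
    means = {"V": 150.0, "C": 150.0, "MALS": 135.0, "UMALS": 140.0,
             "LMALS": 130.0, "LALS": 110.0, "AL2": 145.0}
    return Marginal("normal", means[p.channel], 8.0)


def _draw(rng: np.random.Generator, marg: Marginal, z: np.ndarray) -> np.ndarray:
    """Transform standard-normal draws to the requested marginal."""
    if marg.family == "normal":
        return np.maximum(0.0, marg.mean + marg.sd * z)  # truncate at 0
    sigma2 = math.log1p((marg.sd / marg.mean) ** 2)
    mu = math.log(marg.mean) - sigma2 / 2
    return np.exp(mu + math.sqrt(sigma2) * z)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a cohort deterministically from (config, seed).

    Per-group sample moments converge to the configured marginals as n
    grows; all values are >= 0.  Identical config and seed give
    bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    records: list[CPDRecord] = []
    params = [parse_parameter(name) for name in config.roster]
    for group in config.groups:
        if group.n == 0:
            continue
        factors = {
            cell: rng.standard_normal(group.n) for cell in sorted(group.correlation)
        }
        draws: dict[str, np.ndarray] = {}
        for param in params:
            name = str(param)
            marg = group.overrides.get(name) or config.defaults.get(name) or _default_marginal(name)
            eps = rng.standard_normal(group.n)
            rho = group.correlation.get(param.cell_type, 0.0)
            if rho > 0:
                z = math.sqrt(rho) * factors[param.cell_type] + math.sqrt(1 - rho) * eps
            else:
                z = eps
            draws[name] = _draw(rng, marg, z)
        for i in range(group.n):
            values = {p: float(draws[str(p)][i]) for p in params}
            records.append(
                CPDRecord(f"{group.label}-{i + 1:04d}", values, group.label)
            )
    return Cohort(records, dict(DEFAULT_LABEL_SCHEME))


# --------------------------------------------------------------------------
# The reference study conditions
# --------------------------------------------------------------------------

#: Real cohort sizes of the nine diagnosis groups (total 1348).
GROUP_SIZES = {
    "normal": 1056, "reactive": 47, "AML": 62, "APL": 30, "ALL": 54,
    "lymphoma": 47, "CLL": 28, "CML": 12, "MDS": 12,
}

# Shared marginals: the four screening parameters under the non-neoplastic
# and neoplastic conditions (effect sizes place the published cutoffs near
# the crossing points), and the reactive discriminant MN-AL2-NE.
_NONNEO_SCREEN = {
    "SD-V-NE": Marginal("lognormal", 15.0, 2.2),
    "MN-C-NE": Marginal("normal", 155.0, 4.5),
    "MN-UMALS-LY": Marginal("normal", 52.0, 5.5),
    "SD-AL2-MO": Marginal("lognormal", 13.0, 2.0),
}
_NEO_SCREEN = {
    "SD-V-NE": Marginal("lognormal", 26.0, 5.0),
    "MN-C-NE": Marginal("normal", 142.0, 7.5),
    "MN-UMALS-LY": Marginal("normal", 67.0, 8.5),
    "SD-AL2-MO": Marginal("lognormal", 21.0, 4.5),
}
_AL2_NORMAL = Marginal("normal", 143.0, 6.0)
_AL2_REACTIVE = Marginal("normal", 156.0, 6.0)
_AL2_NEO = Marginal("normal", 141.0, 7.0)

# Baselines shifted so the published subtype cutoffs sit between groups.
_SUBTYPE_BASELINES = {
    "SD-MALS-NE": Marginal("lognormal", 14.0, 3.0),
    "SD-UMALS-NE": Marginal("lognormal", 15.0, 3.0),
    "MN-V-NE": Marginal("normal", 150.0, 8.0),
    "SD-V-MO": Marginal("lognormal", 30.0, 5.0),
    "MN-MALS-NE": Marginal("normal", 126.0, 7.0),
    "MN-LMALS-NE": Marginal("normal", 119.0, 7.0),
    "SD-C-MO": Marginal("lognormal", 9.5, 2.0),
}
_SUBTYPE_SHIFTS: dict[str, dict[str, Marginal]] = {
    "AML": {
        "SD-MALS-NE": Marginal("lognormal", 16.8, 3.2),
        "SD-UMALS-NE": Marginal("lognormal", 18.0, 3.2),
    },
    "APL": {
        "MN-V-NE": Marginal("normal", 158.0, 8.0),
        "SD-V-MO": Marginal("lognormal", 36.0, 6.0),
    },
    "ALL": {
        "MN-MALS-NE": Marginal("normal", 132.0, 8.0),
        "MN-LMALS-NE": Marginal("normal", 126.0, 8.0),
    },
    "CLL": {
        "SD-C-MO": Marginal("lognormal", 11.8, 2.5),
    },
}

SCREENING_PARAMETERS = tuple(_NONNEO_SCREEN)  # ground truth for recovery tests


def paper_like_config(seed: int = 0) -> SimulationConfig:
    """Simulation config emulating the reference study conditions.

    Nine diagnosis groups at real cohort sizes (1348 samples total); the
    four screening parameters separate the neoplastic class strongly
    (per-parameter AUC > 0.9), MN-AL2-NE separates reactive from
    neoplastic, subtype parameters show moderate one-vs-rest shifts, and
    all remaining roster parameters are exchangeable noise.
    """
    defaults = dict(_SUBTYPE_BASELINES)
    groups: list[GroupSpec] = []
    for label, n in GROUP_SIZES.items():
        if label == "normal":
            overrides = {**_NONNEO_SCREEN, "MN-AL2-NE": _AL2_NORMAL}
        elif label == "reactive":
            overrides = {**_NONNEO_SCREEN, "MN-AL2-NE": _AL2_REACTIVE}
        else:
            overrides = {**_NEO_SCREEN, "MN-AL2-NE": _AL2_NEO}
            overrides.update(_SUBTYPE_SHIFTS.get(label, {}))
        groups.append(GroupSpec(label=label, n=n, overrides=overrides))
    return SimulationConfig(groups=groups, seed=seed, defaults=defaults)


def null_config(
    seed: int, n_per_group: int = 60, labels: tuple[str, str] = ("normal", "AML")
) -> SimulationConfig:
    """Two groups with identical distributions for every parameter."""
    groups = [GroupSpec(label=lbl, n=n_per_group) for lbl in labels]
    return SimulationConfig(groups=groups, seed=seed)


# --------------------------------------------------------------------------
# YAML config round-trip
# --------------------------------------------------------------------------

def _marginal_to_list(m: Marginal) -> list:
    return [m.family, m.mean, m.sd]


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    doc = {
        "seed": config.seed,
        "roster": config.roster,
        "defaults": {k: _marginal_to_list(m) for k, m in config.defaults.items()},
        "groups": [
            {
                "label": g.label,
                "n": g.n,
                "overrides": {k: _marginal_to_list(m) for k, m in g.overrides.items()},
                **({"correlation": g.correlation} if g.correlation else {}),
            }
            for g in config.groups
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path, seed: int | None = None) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text())
    groups = [
        GroupSpec(
            label=g["label"],
            n=int(g["n"]),
            overrides={k: Marginal(*v) for k, v in g.get("overrides", {}).items()},
            correlation=dict(g.get("correlation", {})),
        )
        for g in doc["groups"]
    ]
    return SimulationConfig(
        groups=groups,
        seed=int(seed if seed is not None else doc["seed"]),
        roster=list(doc.get("roster") or [str(p) for p in canonical_parameters()]),
        defaults={k: Marginal(*v) for k, v in doc.get("defaults", {}).items()},
    )
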