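"""Synthetic family data with the exact covariance structure the fitters
assume.

The generator emulates a population-survey family sample: ~1,115 small
families (mostly phenotyped pairs, occasionally trios) totalling ~2,250
surveyed individuals, with two correlated thyroid traits (TSH, fT4), the
covariates the analysis adjusts for (age, squared age, sex, BMI, smoking,
menopause, urinary iodine and creatinine, TPOAb), and the exclusion flags
the preparation step consumes.

Families are composed either as sibships (phenotyped siblings whose founder
parents are present in the pedigree but were never surveyed) or as
parent-offspring / nuclear sets in which every member is surveyed.
Unsurveyed founders carry the id suffix ``".u"`` and receive no phenotype
row. Trait vectors are drawn per family block from a zero-mean Gaussian
whose covariance is built from the kinship matrix with the same equations
the fitters use (additive genetic / household / unique environment;
sex-specific variances and cross-sex correlation for the genotype-by-sex
model; 2x2 genetic and environmental correlation structure for the
bivariate model), so generator and likelihood agree by construction. Fixed
covariate effects are added on the latent scale and TSH is mapped through
an exponential so the pipeline's rank-based inverse normal transformation
is exercised non-trivially.

All randomness flows from one explicit seed per dataset; no global RNG
state is touched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "scenario_presets",
    "simulate_pedigrees",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
    "PRESET_NAMES",
]

UNOBSERVED_SUFFIX = ".u"


@dataclass
class SimulationScenario:
    """Everything that defines one simulated study."""

    name: str = "custom"
    n_families: int = 1115
    #: distribution of *surveyed* members per family
    family_sizes: dict[int, float] = field(default_factory=lambda: {2: 0.98, 3: 0.02})
    #: "sibships", "nuclear", or "mixed" (50:50 per family)
    composition: str = "mixed"
    p_male: float = 0.534
    #: "univariate_ace" | "gxs" | "bivariate"
    model: str = "bivariate"
    #: model truth on the latent (covariate-adjusted, unit-variance) scale
    params: dict = field(
        default_factory=lambda: {"h2_1": 0.54, "h2_2": 0.56, "rho_g": 0.0, "rho_e": 0.0}
    )
    #: variance fraction (R^2) each covariate contributes to the latent trait
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.05, "age2": 0.02, "sex": 0.05}
    )
    #: "exp" maps the TSH latent value through an exponential; "identity"
    #: emits the latent scale directly
    trait_transform: str = "exp"
    #: fraction of surveyed rows given an exclusion trigger (TPOAb positive)
    contamination: float = 0.0
    max_block_size: int = 50

    def validate(self) -> None:
        total = sum(self.family_sizes.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"family-size probabilities sum to {total}, not 1")
        if self.composition not in ("sibships", "nuclear", "mixed"):
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.model not in ("univariate_ace", "gxs", "bivariate"):
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.family_sizes) < 2:
            raise ValueError("families must have at least two surveyed members")
        for key, val in self.params.items():
            if key.startswith(("h2", "c2")) and not 0.0 <= val <= 1.0:
                raise ValueError(f"{key}={val} outside [0, 1]")


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: dict


PRESET_NAMES = (
    "knhanes_total",
    "knhanes_gxs",
    "knhanes_bivariate_female",
    "null_gxs",
    "null_pleiotropy",
)


def scenario_presets(name: str) -> SimulationScenario:
    """Named study conditions with literature-scale true parameters.

    ``knhanes_total``: survey-scale bivariate sample, overall heritabilities
    0.54 (TSH) and 0.56 (fT4) with weak negative correlations.
    ``knhanes_gxs``: sex-specific TSH heritabilities 0.41 (male) / 0.75
    (female) with full cross-sex genetic correlation. ``knhanes_bivariate_female``:
    all-female sample with h2 = (0.75, 0.52), rho_g = -0.347, rho_e = 0.367.
    The ``null_*`` presets set the tested effect to its null value.
    """
    base = dict(n_families=1115, family_sizes={2: 0.98, 3: 0.02}, composition="mixed")
    if name == "knhanes_total":
        return SimulationScenario(
            name=name,
            model="bivariate",
            params={"h2_1": 0.54, "h2_2": 0.56, "rho_g": -0.150, "rho_e": -0.056},
            **base,
        )
    if name == "knhanes_gxs":
        return SimulationScenario(
            name=name,
            model="gxs",
            params={"h2_m": 0.41, "h2_f": 0.75, "rho_gmf": 1.0},
            **base,
        )
    if name == "knhanes_bivariate_female":
        cfg = dict(base)
        cfg["composition"] = "sibships"  # keeps every surveyed member female
        return SimulationScenario(
            name=name,
            model="bivariate",
            p_male=0.0,
            params={"h2_1": 0.75, "h2_2": 0.52, "rho_g": -0.347, "rho_e": 0.367},
            **cfg,
        )
    if name == "null_gxs":
        return SimulationScenario(
            name=name,
            model="gxs",
            params={"h2_m": 0.54, "h2_f": 0.54, "rho_gmf": 1.0},
            **base,
        )
    if name == "null_pleiotropy":
        return SimulationScenario(
            name=name,
            model="bivariate",
            params={"h2_1": 0.54, "h2_2": 0.56, "rho_g": 0.0, "rho_e": 0.0},
            **base,
        )
    raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def _draw_sex(rng, p_male: float) -> str:
    return "male" if rng.random() < p_male else "female"


def simulate_pedigrees(scenario: SimulationScenario, seed: int) -> Pedigree:
    """Draw a pedigree of independent families; deterministic given seed."""
    scenario.validate()
    rng = np.random.default_rng(seed)
    sizes = np.array(sorted(scenario.family_sizes))
    probs = np.array([scenario.family_sizes[s] for s in sizes], dtype=float)
    individuals: list[Individual] = []
    for f in range(scenario.n_families):
        fam = f"F{f + 1:05d}"
        k = int(rng.choice(sizes, p=probs))
        comp = scenario.composition
        if comp == "mixed":
            comp = "sibships" if rng.random() < 0.5 else "nuclear"
        individuals.extend(_make_family(fam, k, comp, rng, scenario.p_male))
    return Pedigree(individuals)


def _make_family(fam, k, comp, rng, p_male) -> list[Individual]:
    if comp == "sibships":
        father = Individual(f"{fam}.f{UNOBSERVED_SUFFIX}", fam, None, None, "male")
        mother = Individual(f"{fam}.m{UNOBSERVED_SUFFIX}", fam, None, None, "female")
        sibs = [
            Individual(f"{fam}.{i + 1}", fam, father.id, mother.id, _draw_sex(rng, p_male))
            for i in range(k)
        ]
        return [father, mother] + sibs
    if k < 2:
        raise ValueError("a nuclear family needs at least two surveyed members")
    if k == 2:  # one surveyed parent plus one child; other parent unknown
        psex = _draw_sex(rng, p_male)
        parent = Individual(f"{fam}.p", fam, None, None, psex)
        child = Individual(
            f"{fam}.1",
            fam,
            parent.id if psex == "male" else None,
            parent.id if psex == "female" else None,
            _draw_sex(rng, p_male),
        )
        return [parent, child]
    father = Individual(f"{fam}.f", fam, None, None, "male")
    mother = Individual(f"{fam}.m", fam, None, None, "female")
    kids = [
        Individual(f"{fam}.{i + 1}", fam, father.id, mother.id, _draw_sex(rng, p_male))
        for i in range(k - 2)
    ]
    return [father, mother] + kids


def observed_mask(ped: Pedigree) -> np.ndarray:
    """True for individuals that were surveyed (phenotype rows exist)."""
    return np.array(
        [not ind.id.endswith(UNOBSERVED_SUFFIX) for ind in ped.individuals],
        dtype=bool,
    )


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

# latent -> reported scale maps; medians/spreads chosen to land inside the
# adult reference intervals (TSH skewed, fT4 roughly symmetric)
_TSH_LOC, _TSH_SCALE = 0.35, 0.45
_FT4_LOC, _FT4_SCALE = 1.30, 0.13

# analytic SDs of the covariate distributions used below
_COV_SD = {"age": 18.0, "age2": 430.0, "sex": 0.5, "bmi": 3.2}


def _latent_cov(scenario, phi2: np.ndarray, male: np.ndarray):
    """Per-block covariance (or pair of them) of the latent trait(s)."""
    k = phi2.shape[0]
    p = scenario.params
    if scenario.model == "univariate_ace":
        h2 = p.get("h2", p.get("h2_1", 0.5))
        c2 = p.get("c2", 0.0)
        e2 = 1.0 - h2 - c2
        sig = h2 * phi2 + c2 * np.ones((k, k)) + e2 * np.eye(k)
        return [sig, sig]
    if scenario.model == "gxs":
        sd = np.where(male, np.sqrt(p["h2_m"]), np.sqrt(p["h2_f"]))
        opp = male[:, None] != male[None, :]
        corr = np.where(opp, p["rho_gmf"], 1.0)
        e2 = np.where(male, 1.0 - p["h2_m"], 1.0 - p["h2_f"])
        sig = phi2 * np.outer(sd, sd) * corr + np.diag(e2)
        return [sig, sig]
    # bivariate
    g12 = p["rho_g"] * np.sqrt(p["h2_1"] * p["h2_2"])
    e12 = p["rho_e"] * np.sqrt((1 - p["h2_1"]) * (1 - p["h2_2"]))
    G = np.array([[p["h2_1"], g12], [g12, p["h2_2"]]])
    E = np.array([[1 - p["h2_1"], e12], [e12, 1 - p["h2_2"]]])
    sig = np.kron(phi2, G) + np.kron(np.eye(k), E)
    return sig


def simulate_phenotypes(
    ped: Pedigree, scenario: SimulationScenario, seed: int
) -> pd.DataFrame:
    """Simulate the phenotype table for the surveyed members of ``ped``."""
    scenario.validate()
    rng = np.random.default_rng(seed)
    obs = observed_mask(ped)
    sexes = ped.sexes  # 1 = male
    n = len(ped)

    age = np.where(
        [ind.father_id is None and ind.mother_id is None for ind in ped.individuals],
        rng.uniform(35.0, 80.0, n),
        rng.uniform(10.0, 55.0, n),
    )
    bmi = np.clip(rng.normal(23.5, 3.2, n), 15.0, 40.0)
    smoking = np.where(
        rng.random(n) < np.where(sexes == 1, 0.38, 0.06), "current", "never"
    )
    menopause = np.where((sexes == 0) & (age >= 50.0), "yes", "no")
    ui = rng.lognormal(np.log(300.0), 1.0, n)
    ucr = rng.lognormal(np.log(120.0), 0.6, n)
    tpoab = rng.lognormal(np.log(8.0), 0.5, n)
    if scenario.contamination > 0:
        hit = rng.random(n) < scenario.contamination
        tpoab = np.where(hit, 60.0, tpoab)

    eff = scenario.covariate_effects
    age_c = age - 45.0
    fixed = np.zeros(n)
    fixed += np.sqrt(eff.get("age", 0.0)) / _COV_SD["age"] * age_c
    fixed += np.sqrt(eff.get("age2", 0.0)) / _COV_SD["age2"] * (age_c**2 - age_c.var())
    fixed += np.sqrt(eff.get("sex", 0.0)) / _COV_SD["sex"] * (sexes - 0.5)
    fixed += np.sqrt(eff.get("bmi", 0.0)) / _COV_SD["bmi"] * (bmi - 23.5)

    z = np.full((n, 2), np.nan)
    for block in ped.blocks:
        members = block[obs[block]]
        k = members.size
        if k == 0:
            continue
        if k > scenario.max_block_size:
            raise ValueError(f"block of {k} exceeds max_block_size")
        phi2 = 2.0 * ped.kinship(members)
        male = sexes[members] == 1
        cov = _latent_cov(scenario, phi2, male)
        if isinstance(cov, list):  # one trait at a time, independent draws
            for t in range(2):
                z[members, t] = _mvn(rng, cov[t])
        else:  # bivariate: interleaved (individual-major) vector
            draw = _mvn(rng, cov)
            z[members, 0] = draw[0::2]
            z[members, 1] = draw[1::2]
    z += fixed[:, None]

    if scenario.trait_transform == "exp":
        tsh = np.exp(_TSH_LOC + _TSH_SCALE * z[:, 0])
        ft4 = _FT4_LOC + _FT4_SCALE * z[:, 1]
    elif scenario.trait_transform == "identity":
        tsh, ft4 = z[:, 0], z[:, 1]
    else:
        raise ValueError(f"unknown trait transform {scenario.trait_transform!r}")

    df = pd.DataFrame(
        {
            "id": ped.ids,
            "family_id": [ind.family_id for ind in ped.individuals],
            "sex": np.where(sexes == 1, "male", "female"),
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "smoking": smoking,
            "menopause": menopause,
            "ui": ui,
            "ucr": ucr,
            "tpoab": tpoab,
            "tsh": tsh,
            "ft4": ft4,
            "overt_dysfunction": False,
            "prior_treatment": False,
            "pregnant": False,
            "thyroid_history": False,
            "family_history": False,
        }
    )
    return df.loc[obs].reset_index(drop=True)


def _mvn(rng, cov: np.ndarray) -> np.ndarray:
    """Draw one zero-mean Gaussian vector via the matrix square root."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        # PSD-but-singular truth covariances (e.g. rho = 1) via eigh
        w, v = np.linalg.eigh(cov)
        if np.any(w < -1e-8):
            raise ValueError("truth covariance is not positive semidefinite") from exc
        chol = v * np.sqrt(np.clip(w, 0.0, None))
    return chol @ rng.standard_normal(cov.shape[0])


def simulate_dataset(scenario: SimulationScenario, seed: int) -> SimulatedDataset:
    """Pedigree + phenotypes + truth record from one seed."""
    ss = np.random.SeedSequence(seed)
    s_ped, s_phen = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    ped = simulate_pedigrees(scenario, s_ped)
    phen = simulate_phenotypes(ped, scenario, s_phen)
    truth = {"scenario": asdict(scenario), "seed": int(seed)}
    truth["scenario"]["family_sizes"] = {
        str(k): v for k, v in scenario.family_sizes.items()
    }
    return SimulatedDataset(pedigree=ped, phenotypes=phen, truth=truth)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write pedigree.tsv, phenotypes.csv and truth.json under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ped_path = os.path.join(outdir, "pedigree.tsv")
    rows = [
        "\t".join(
            [
                ind.family_id,
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                "1" if ind.sex == "male" else "2",
            ]
        )
        for ind in ds.pedigree.individuals
    ]
    with open(ped_path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    phen_path = os.path.join(outdir, "phenotypes.csv")
    ds.phenotypes.to_csv(phen_path, index=False)
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    return {"pedigree": ped_path, "phenotypes": phen_path, "truth": truth_path}
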