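"""Synthetic MZ-twin cohort generator.

Emulates the statistical structure the enterotype analysis assumes, so the
whole pipeline is testable without any sequence data:

* each twin pair draws a latent enterotype for the index twin
  (P(enterotype 2) = ``pi2``); the co-twin copies it with probability
  ``rho_conc``, otherwise flips;
* longitudinally sampled subjects keep their enterotype at the second time
  point with probability ``rho_pers`` (a symmetric two-state step);
* genus and KEGG-pathway profiles are exact Dirichlet draws from the
  latent enterotype's concentration vector (enterotype 1 Bacteroides-heavy,
  enterotype 2 Prevotella-heavy); an optional multinomial read-resampling
  layer adds count noise but is off by default;
* clinical traits are Gaussian with an enterotype-2 mean shift only for
  serum uric acid; nutrient intakes are linear in total energy intake with
  enterotype-2 shifts for the nine diet variables the analysis targets
  (fiber, potassium, iron, vitamins A/C/E, folate, carotene, retinol).

Defaults mirror a 10-pair cohort with 8 pairs sampled at both of two time
points (36 samples), co-twin concordance 0.722 and two-year persistency
0.813.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import AbundanceTable, MetadataTable, TwinDesign, ValidationError

DEFAULT_GENERA = [
    "Bacteroides", "Prevotella", "Catenibacterium", "Lactobacillus", "Dorea",
    "Coprococcus", "Faecalibacterium", "Roseburia", "Ruminococcus", "Alistipes",
    "Blautia", "Bifidobacterium", "Akkermansia", "Eubacterium", "Clostridium",
    "Parabacteroides", "Oscillibacter", "Dialister", "Phascolarctobacterium",
    "Megamonas", "Sutterella", "Veillonella", "Streptococcus", "Collinsella",
    "Odoribacter", "Butyrivibrio", "Anaerostipes", "Subdoligranulum",
    "Paraprevotella", "Fusobacterium",
]

DEFAULT_PATHWAYS = [f"ko{10 * (i + 1):05d}" for i in range(20)]

# nine nutrients the analysis expects to shift with enterotype 2, plus fillers
ASSOCIATED_NUTRIENTS = [
    "fiber", "potassium", "iron", "vitamin_a", "vitamin_c", "vitamin_e",
    "folate", "carotene", "retinol",
]
FILLER_NUTRIENTS = [
    "protein", "fat", "carbohydrate", "calcium", "phosphorus", "sodium",
    "zinc", "magnesium", "vitamin_b1", "vitamin_b2", "vitamin_b6", "niacin",
    "vitamin_d", "cholesterol",
]
DEFAULT_NUTRIENTS = ASSOCIATED_NUTRIENTS + FILLER_NUTRIENTS  # 23 in total

DEFAULT_FOOD_GROUPS = [
    "grain", "rice", "noodles", "bread", "potato", "legume", "nut",
    "vegetable", "kimchi", "mushroom", "fruit", "meat", "poultry", "egg",
    "fish", "shellfish", "seaweed", "dairy", "milk", "yogurt", "oil",
    "sugar", "confectionery", "beverage", "coffee", "tea", "alcohol",
    "soup", "seasoning", "snack",
]

# (baseline mean, sd, enterotype-2 shift) in original clinical units
DEFAULT_TRAIT_EFFECTS = {
    "age": (40.0, 6.0, 0.0),
    "bmi": (24.0, 3.0, 0.0),
    "systolic_bp": (120.0, 12.0, 0.0),
    "glucose": (95.0, 10.0, 0.0),
    "total_cholesterol": (190.0, 30.0, 0.0),
    "triglyceride": (130.0, 60.0, 0.0),
    "uric_acid": (5.0, 1.2, 1.8),
}


def _dirichlet_alpha(
    heavy: dict[str, float], features: list[str], concentration: float
) -> np.ndarray:
    """Concentration vector: named proportions + uniform filler mass."""
    props = np.zeros(len(features))
    named = 0.0
    for name, mass in heavy.items():
        props[features.index(name)] = mass
        named += mass
    filler = (1.0 - named) / (props == 0).sum()
    props[props == 0] = filler
    return props * concentration


def default_genus_alphas(concentration: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    a1 = _dirichlet_alpha(
        {"Bacteroides": 0.45, "Prevotella": 0.02, "Catenibacterium": 0.03,
         "Lactobacillus": 0.005, "Dorea": 0.005, "Coprococcus": 0.005},
        DEFAULT_GENERA, concentration,
    )
    a2 = _dirichlet_alpha(
        {"Prevotella": 0.45, "Bacteroides": 0.05, "Catenibacterium": 0.005,
         "Lactobacillus": 0.03, "Dorea": 0.03, "Coprococcus": 0.03},
        DEFAULT_GENERA, concentration,
    )
    return a1, a2


def default_kegg_alphas(concentration: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    k1 = _dirichlet_alpha(
        {p: 0.10 for p in DEFAULT_PATHWAYS[:5]}, DEFAULT_PATHWAYS, concentration
    )
    k2 = _dirichlet_alpha(
        {p: 0.10 for p in DEFAULT_PATHWAYS[5:10]}, DEFAULT_PATHWAYS, concentration
    )
    return k1, k2


def default_nutrient_effects() -> dict[str, tuple[float, float, float]]:
    """Per-nutrient (energy slope, enterotype-2 shift, noise sd)."""
    effects = {n: (0.01, 0.0, 1.0) for n in DEFAULT_NUTRIENTS}
    for n in ASSOCIATED_NUTRIENTS:
        effects[n] = (0.01, 2.0, 1.0)
    return effects


@dataclass
class CohortSpec:
    """Design parameters of a synthetic MZ twin cohort."""

    n_pairs: int = 10
    p_longitudinal: float = 0.8
    pi2: float = 0.583  # marginal probability of enterotype 2
    rho_conc: float = 0.722  # co-twin shares the index twin's enterotype
    rho_pers: float = 0.813  # subject keeps its enterotype at time 2
    genera: list[str] = field(default_factory=lambda: list(DEFAULT_GENERA))
    alpha1: np.ndarray | None = None
    alpha2: np.ndarray | None = None
    pathways: list[str] = field(default_factory=lambda: list(DEFAULT_PATHWAYS))
    kegg_alpha1: np.ndarray | None = None
    kegg_alpha2: np.ndarray | None = None
    trait_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_EFFECTS)
    )
    nutrient_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=default_nutrient_effects
    )
    food_groups: list[str] = field(default_factory=lambda: list(DEFAULT_FOOD_GROUPS))
    energy_mean: float = 2000.0  # kcal/day
    energy_sd: float = 300.0
    n_diet_missing: int = 4  # samples lacking the diet block entirely
    read_depth: int | None = None  # multinomial resampling depth (off by default)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_longitudinal", "pi2", "rho_conc", "rho_pers"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.alpha1 is None or self.alpha2 is None:
            if self.genera != DEFAULT_GENERA:
                raise ValidationError("custom genus list requires explicit alpha vectors")
            self.alpha1, self.alpha2 = default_genus_alphas()
        if self.kegg_alpha1 is None or self.kegg_alpha2 is None:
            if self.pathways != DEFAULT_PATHWAYS:
                raise ValidationError("custom pathway list requires explicit alpha vectors")
            self.kegg_alpha1, self.kegg_alpha2 = default_kegg_alphas()
        for name, alpha, labels in (
            ("alpha1", self.alpha1, self.genera),
            ("alpha2", self.alpha2, self.genera),
            ("kegg_alpha1", self.kegg_alpha1, self.pathways),
            ("kegg_alpha2", self.kegg_alpha2, self.pathways),
        ):
            alpha = np.asarray(alpha, dtype=float)
            if len(alpha) != len(labels):
                raise ValidationError(f"{name} length {len(alpha)} != {len(labels)} features")
            if (alpha <= 0).any():
                raise ValidationError(f"{name} must be strictly positive")
            setattr(self, name, alpha)


@dataclass
class Cohort:
    """A generated cohort with its latent per-sample enterotype truth."""

    genus: AbundanceTable
    kegg: AbundanceTable
    design: TwinDesign
    metadata: MetadataTable
    truth: pd.DataFrame  # sample_id, subject_id, pair_id, time_point, enterotype


def generate_twin_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic twin cohort from the spec's generative model.

    Bit-identical output for identical specs (single seeded RNG, fixed draw
    order).  The number of longitudinal pairs is the deterministic count
    ``round(p_longitudinal * n_pairs)`` (the first pairs in order), so the
    design shape does not vary between seeds.
    """
    rng = np.random.default_rng(spec.seed)
    n_long = int(round(spec.p_longitudinal * spec.n_pairs))

    rows = []  # sample_id, subject_id, pair_id, time_point, enterotype
    for p in range(spec.n_pairs):
        pair_id = f"P{p + 1:03d}"
        e_index = 2 if rng.random() < spec.pi2 else 1
        e_cotwin = e_index if rng.random() < spec.rho_conc else 3 - e_index
        longitudinal = p < n_long
        for twin, e_t1 in (("A", e_index), ("B", e_cotwin)):
            subject = f"{pair_id}{twin}"
            states = {1: e_t1}
            if longitudinal:
                states[2] = e_t1 if rng.random() < spec.rho_pers else 3 - e_t1
            for tp, e in states.items():
                rows.append((f"{subject}T{tp}", subject, pair_id, tp, e))

    truth = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "pair_id", "time_point", "enterotype"]
    )
    design = TwinDesign(truth[["sample_id", "subject_id", "pair_id", "time_point"]].copy())
    sample_ids = truth["sample_id"].tolist()
    enterotypes = truth["enterotype"].to_numpy()
    n = len(sample_ids)

    def draw_profiles(a1: np.ndarray, a2: np.ndarray, labels: list[str]) -> pd.DataFrame:
        X = np.empty((n, len(labels)))
        for i, e in enumerate(enterotypes):
            X[i] = rng.dirichlet(a1 if e == 1 else a2)
        if spec.read_depth is not None:
            counts = np.vstack([rng.multinomial(spec.read_depth, row) for row in X])
            X = counts / spec.read_depth
        return pd.DataFrame(X, index=sample_ids, columns=labels)

    genus = AbundanceTable(draw_profiles(spec.alpha1, spec.alpha2, spec.genera), level="genus")
    kegg = AbundanceTable(
        draw_profiles(spec.kegg_alpha1, spec.kegg_alpha2, spec.pathways), level="kegg_pathway"
    )

    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    is_e2 = (enterotypes == 2).astype(float)
    for trait, (mean, sd, shift) in spec.trait_effects.items():
        meta[trait] = mean + shift * is_e2 + rng.normal(0.0, sd, size=n)
    for group in spec.food_groups:
        meta[f"food_{group}"] = rng.lognormal(mean=3.5, sigma=0.8, size=n)
    energy = np.maximum(rng.normal(spec.energy_mean, spec.energy_sd, size=n), 500.0)
    meta["energy"] = energy
    for nutrient, (slope, shift, sd) in spec.nutrient_effects.items():
        value = slope * energy + shift * is_e2 + rng.normal(0.0, sd, size=n)
        meta[f"nutrient_{nutrient}"] = np.maximum(value, 0.0)

    if spec.n_diet_missing > 0:
        diet_cols = (
            [f"food_{g}" for g in spec.food_groups]
            + ["energy"]
            + [f"nutrient_{x}" for x in spec.nutrient_effects]
        )
        missing = rng.choice(n, size=min(spec.n_diet_missing, n), replace=False)
        meta.loc[meta.index[missing], diet_cols] = np.nan

    metadata = MetadataTable(
        meta,
        trait_cols=list(spec.trait_effects),
        food_cols=[f"food_{g}" for g in spec.food_groups],
        nutrient_cols=[f"nutrient_{x}" for x in spec.nutrient_effects],
        energy_col="energy",
    )
    return Cohort(genus=genus, kegg=kegg, design=design, metadata=metadata, truth=truth)


def summarize_truth(truth: pd.DataFrame) -> dict:
    """Design-level summary of the latent enterotypes.

    Reports enterotype frequencies, concordant/discordant paired-observation
    counts and longitudinal switch counts, consistent with the design
    cardinalities.
    """
    if truth.empty:
        return {
            "n_samples": 0, "enterotype_counts": {}, "n_paired_observations": 0,
            "n_concordant": 0, "n_discordant": 0, "n_longitudinal_subjects": 0,
            "n_switched": 0,
        }
    counts = truth["enterotype"].value_counts().sort_index().to_dict()
    n_conc = n_disc = n_paired = 0
    for _, grp in truth.groupby(["pair_id", "time_point"]):
        if grp["subject_id"].nunique() != 2:
            continue
        n_paired += 1
        if grp["enterotype"].nunique() == 1:
            n_conc += 1
        else:
            n_disc += 1
    wide = truth.pivot(index="subject_id", columns="time_point", values="enterotype")
    if 1 in wide.columns and 2 in wide.columns:
        both = wide.dropna(subset=[1, 2])
        n_long = len(both)
        n_switch = int((both[1] != both[2]).sum())
    else:
        n_long = n_switch = 0
    return {
        "n_samples": len(truth),
        "enterotype_counts": {int(k): int(v) for k, v in counts.items()},
        "n_paired_observations": n_paired,
        "n_concordant": n_conc,
        "n_discordant": n_disc,
        "n_longitudinal_subjects": n_long,
        "n_switched": n_switch,
    }


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """A copy of ``spec`` with a different RNG seed."""
    return replace(spec, seed=seed)
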