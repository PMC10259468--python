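"""Synthetic paired diet/consumer metabolome generator.

Emulates, at the aligned-feature-table level, an experiment in which a
single founder insect population is reared on four fruit media, with
control individuals on the artificial medium alone and blank solvent
injections: 4 fruits x 3 puree replicates; fly pools for 4 diets x 2
generations x 3 replicates (blackcurrant: one generation only); control
flies per generation; and ~10^3-10^4 ions partitioned into planted
classes with log-normal intensities, a multiplicative generation batch
effect and a hard detection floor.

Every ion carries a ground-truth class that prescribes exactly where it
is present:

================== =============================================================
class              present in
================== =============================================================
core_shared        all fruits and all fruit-fed flies
fruit_only_shared  all fruits, no flies
fruit_private      one fruit only (not transferred)
transferred_private one fruit and the flies reared on it
fly_de_novo_common all fruit-fed flies only (diet-induced metabolites,
                   absent from control flies)
diet_signature     the focal fruit and all flies, with peak areas elevated
                   by ``effect_size`` in flies reared on the focal diet
artificial_medium  control flies and all fruit-fed flies (medium-derived;
                   cancelled by control-median correction)
blank_contaminant  every sample, with the blank injections higher still
                   (removed by blank suppression)
================== =============================================================

Quantitative fruit-to-fruit structure for ions shared by several fruits
follows Brownian motion along a configurable "chemical proximity" tree,
so that hierarchical clustering of fruit samples has a planted topology
that can agree with, or deliberately violate, the species phylogeny.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core import DIETS, FeatureTable, StudyDesign, format_ion_id, IonID

__all__ = [
    "SynthConfig",
    "IonTruth",
    "make_default_config",
    "generate_truth",
    "simulate_feature_tables",
    "simulate",
    "truth_frame",
    "simulate_quantitative_contrast",
    "PHYLOGENY_NEWICK",
    "DEFAULT_CHEMICAL_NEWICK",
    "ION_CLASSES",
]

#: Species phylogeny of the four fruits: cherry and strawberry are
#: Rosaceae (Rosids), cranberry Ericaceae (Asterids), blackcurrant
#: Grossulariaceae (Saxifragales).  Ultrametric branch lengths so the
#: tree can also serve as a planted chemical-proximity structure.
PHYLOGENY_NEWICK = "(((cherry:1,strawberry:1):1,cranberry:2):1,blackcurrant:3);"

#: Default planted chemical-proximity tree.  It deliberately differs
#: from the phylogeny (cherry does not pair with strawberry), emulating
#: the observation that taxonomy need not predict chemical proximity:
#: blackcurrant is chemically the most distinct fruit.
DEFAULT_CHEMICAL_NEWICK = "(((cranberry:1,strawberry:1):1,cherry:2):1,blackcurrant:3);"

ION_CLASSES = (
    "core_shared",
    "fruit_only_shared",
    "fruit_private",
    "transferred_private",
    "fly_de_novo_common",
    "diet_signature",
    "artificial_medium",
    "blank_contaminant",
)

_PER_DIET_CLASSES = ("fruit_private", "transferred_private", "diet_signature")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the generator; defaults via :func:`make_default_config`."""

    n_ions: int
    class_fractions: dict[str, float]
    design: StudyDesign
    base_log_mean: float = math.log(5e4)
    log_sd: float = 0.3
    generation_effect: float = 1.5
    dropout_area: float = 500.0
    seed: int = 0
    effect_size: float = 4.0
    #: per-ion spread of baseline log abundance (structural, not sample noise)
    ion_spread: float = 0.8
    #: planted-present cells never have mean area below this (keeps the
    #: planted presence pattern identifiable by the >1000 rule)
    presence_floor: float = 5000.0
    #: medium-derived ions sit at moderate abundance so that control-median
    #: centering pushes them below the removal threshold
    artificial_log_mean: float = math.log(4000.0)
    #: technical scatter of medium-derived ions around the shared
    #: per-generation medium level; None -> log_sd / 6
    medium_technical_sd: float | None = None
    blank_factor: float = 4.0
    n_blank_injections: int = 2
    chemical_tree: str | None = DEFAULT_CHEMICAL_NEWICK
    chemical_branch_sd: float = 0.6
    positive_mode_fraction: float = 0.68

    def __post_init__(self) -> None:
        if self.n_ions < 1:
            raise ValueError("n_ions must be >= 1")
        if self.dropout_area < 0:
            raise ValueError("dropout_area must be >= 0")
        fr = self.class_fractions
        unknown = set(fr) - set(ION_CLASSES)
        if unknown:
            raise ValueError(f"unknown ion classes: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fr.values())}")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")

    @property
    def technical_sd(self) -> float:
        return self.log_sd / 6.0 if self.medium_technical_sd is None else self.medium_technical_sd


@dataclass(frozen=True)
class IonTruth:
    """Ground-truth record for one simulated ion."""

    ion_id: str
    mz: float
    rt: float
    mode: str
    ion_class: str
    diet: str | None  # set for per-diet classes, else None
    effect_size: float

    def __post_init__(self) -> None:
        if self.ion_class in _PER_DIET_CLASSES and self.diet is None:
            raise ValueError(f"{self.ion_class} requires a diet label")
        if self.ion_class not in _PER_DIET_CLASSES and self.diet is not None:
            raise ValueError(f"{self.ion_class} must not carry a diet label")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")


def make_default_config(seed: int) -> SynthConfig:
    """Default study conditions: the reference design at desk scale.

    Class fractions are calibrated to the published shares of the study
    system: the all-fruit/all-fly core is the largest class, ~10% of all
    ions are fly metabolites never seen in fruits, and each fruit keeps
    a private complement of a few percent.
    """
    fractions = {
        "core_shared": 0.45,
        "fruit_only_shared": 0.05,
        "fruit_private": 0.20,
        "transferred_private": 0.04,
        "fly_de_novo_common": 0.10,
        "diet_signature": 0.04,
        "artificial_medium": 0.06,
        "blank_contaminant": 0.06,
    }
    return SynthConfig(
        n_ions=2000,
        class_fractions=fractions,
        design=StudyDesign(),
        seed=int(seed),
    )


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion `total` into integer counts proportional to `weights`."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        raise ValueError("weights must not all be zero")
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = total - counts.sum()
    # ties broken by position: stable argsort on negated remainders
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_truth(config: SynthConfig) -> list[IonTruth]:
    """Draw ion identities and planted classes; deterministic given seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(config.seed), 0)))
    fractions = np.array([config.class_fractions.get(c, 0.0) for c in ION_CLASSES])
    class_counts = _largest_remainder(config.n_ions, fractions)

    diets = config.design.diets
    records: list[tuple[str, str | None]] = []
    for cls, count in zip(ION_CLASSES, class_counts):
        if cls in _PER_DIET_CLASSES:
            per_diet = _largest_remainder(int(count), np.ones(len(diets)))
            for diet, c in zip(diets, per_diet):
                records.extend((cls, diet) for _ in range(c))
        else:
            records.extend((cls, None) for _ in range(count))

    seen: set[str] = set()
    truth: list[IonTruth] = []
    for cls, diet in records:
        while True:
            mz = round(float(rng.uniform(95.0, 1200.0)), 4)
            rt = round(float(rng.uniform(0.0, 600.0)), 1)
            mode = "pos" if rng.random() < config.positive_mode_fraction else "neg"
            ion_id = format_ion_id(IonID(mz=mz, rt=rt, mode=mode))
            if ion_id not in seen:
                seen.add(ion_id)
                break
        truth.append(
            IonTruth(
                ion_id=ion_id,
                mz=mz,
                rt=rt,
                mode=mode,
                ion_class=cls,
                diet=diet,
                effect_size=config.effect_size if cls == "diet_signature" else 1.0,
            )
        )
    return truth


def truth_frame(truth: list[IonTruth]) -> pd.DataFrame:
    """Tabulate ground truth (one row per ion, indexed by ion id)."""
    df = pd.DataFrame([t.__dict__ for t in truth])
    return df.set_index("ion_id")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _sample_sheet(config: SynthConfig) -> pd.DataFrame:
    design = config.design
    rows = []
    for diet in design.diets:
        for r in range(1, design.fruit_reps + 1):
            rows.append((f"fruit_{diet}_r{r}", "fruit", diet, None, r))
    for diet in design.diets:
        for g in design.generations_for(diet):
            for r in range(1, design.fly_reps + 1):
                rows.append((f"fly_{diet}_g{g}_r{r}", "fly", diet, g, r))
    if design.has_controls:
        for g in range(1, design.n_generations + 1):
            for r in range(1, design.fly_reps + 1):
                rows.append((f"ctrl_g{g}_r{r}", "control_fly", None, g, r))
    if design.has_blank:
        for r in range(1, config.n_blank_injections + 1):
            rows.append((f"blank_r{r}", "blank", None, None, r))
    return pd.DataFrame(rows, columns=["sample_id", "kind", "diet", "generation", "replicate"])


def _brownian_leaf_offsets(
    newick: str, diets: tuple[str, ...], n: int, sd: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-fruit log-abundance offsets from Brownian motion on a tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if leaves != sorted(diets):
        raise ValueError(f"chemical tree leaves {leaves} do not match diets {sorted(diets)}")
    offsets: dict = {tree.seed_node: np.zeros(n)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length if node.edge.length is not None else 1.0
        offsets[node] = offsets[node.parent_node] + rng.normal(0.0, sd * math.sqrt(length), n)
    return {leaf.taxon.label: offsets[leaf] for leaf in tree.leaf_node_iter()}


def _present_pattern(t: IonTruth, diets: tuple[str, ...]):
    """(fruit diets, fly diets, in controls, in blank) where the ion is present."""
    all_d = set(diets)
    cls = t.ion_class
    if cls == "core_shared":
        return all_d, all_d, False, False
    if cls == "fruit_only_shared":
        return all_d, set(), False, False
    if cls == "fruit_private":
        return {t.diet}, set(), False, False
    if cls == "transferred_private":
        return {t.diet}, {t.diet}, False, False
    if cls == "fly_de_novo_common":
        return set(), all_d, False, False
    if cls == "diet_signature":
        return {t.diet}, all_d, False, False
    if cls == "artificial_medium":
        return set(), all_d, True, False
    if cls == "blank_contaminant":
        return all_d, all_d, True, True
    raise ValueError(f"unknown ion class {cls!r}")


def simulate_feature_tables(truth: list[IonTruth], config: SynthConfig) -> FeatureTable:
    """Simulate the integral feature table (fruits + flies + controls + blanks).

    Areas are log-normal around class-dependent means; planted-absent
    cells are exactly 0; values below ``dropout_area`` are floored to 0.
    Deterministic given (truth, config).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(config.seed), 1)))
    n = len(truth)
    diets = config.design.diets
    samples = _sample_sheet(config)
    classes = np.array([t.ion_class for t in truth])
    ion_diet = np.array([t.diet if t.diet is not None else "" for t in truth])

    # structural baseline per ion
    base = config.base_log_mean + rng.normal(0.0, config.ion_spread, n)
    floor = math.log(config.presence_floor)
    log_ge = math.log(config.generation_effect)

    # quantitative fruit structure for multi-fruit classes
    multi_fruit = np.isin(classes, ["core_shared", "fruit_only_shared"])
    if config.chemical_tree is not None:
        leaf_off = _brownian_leaf_offsets(
            config.chemical_tree, diets, n, config.chemical_branch_sd, rng
        )
    else:
        leaf_off = {d: np.zeros(n) for d in diets}

    # medium-derived ions: shared per-(ion, generation) medium level
    artificial = classes == "artificial_medium"
    art_base = np.clip(
        config.artificial_log_mean + rng.normal(0.0, 0.3, n),
        math.log(2000.0),
        math.log(10000.0),
    )
    n_gen = config.design.n_generations
    medium_level = np.empty((n, n_gen))
    for g in range(n_gen):
        medium_level[:, g] = (
            art_base + config.log_sd * rng.standard_normal(n) + g * log_ge
        )

    present = {t.ion_id: _present_pattern(t, diets) for t in truth}
    ion_ids = [t.ion_id for t in truth]
    signature = classes == "diet_signature"
    log_effect = math.log(config.effect_size)

    areas = np.zeros((n, len(samples)))
    for j, row in samples.iterrows():
        kind, diet, gen = row["kind"], row["diet"], row["generation"]
        mean = np.full(n, -np.inf)
        if kind == "fruit":
            mask = np.array([diet in present[i][0] for i in ion_ids])
            m = base + leaf_off[diet] * multi_fruit
            mean[mask] = np.maximum(m[mask], floor)
        elif kind in ("fly", "control_fly"):
            gen = int(gen)
            if kind == "fly":
                mask = np.array([diet in present[i][1] for i in ion_ids])
            else:
                mask = np.array([present[i][2] for i in ion_ids])
            m = np.maximum(base, floor) + (gen - 1) * log_ge
            if kind == "fly":
                m = m + log_effect * (signature & (ion_diet == diet))
            # blank contaminants are instrument background: no batch factor
            m[classes == "blank_contaminant"] = base[classes == "blank_contaminant"]
            # medium-derived ions follow the shared medium level of the batch
            m[artificial] = medium_level[artificial, gen - 1]
            mean[mask] = m[mask]
        elif kind == "blank":
            mask = classes == "blank_contaminant"
            mean[mask] = base[mask] + math.log(config.blank_factor)
        noise_sd = np.full(n, config.log_sd)
        if kind in ("fly", "control_fly"):
            noise_sd[artificial] = config.technical_sd
        vals = np.exp(mean + noise_sd * rng.standard_normal(n))
        vals[~mask] = 0.0
        vals[vals < config.dropout_area] = 0.0
        areas[:, j] = vals

    table = pd.DataFrame(areas, index=ion_ids, columns=samples["sample_id"])
    return FeatureTable(areas=table, samples=samples)


def simulate(config: SynthConfig) -> tuple[FeatureTable, list[IonTruth]]:
    """Generate truth and the matching integral table in one call."""
    truth = generate_truth(config)
    return simulate_feature_tables(truth, config), truth


# ---------------------------------------------------------------------------
# purely quantitative diet signal (resolving-power contrast)
# ---------------------------------------------------------------------------


def simulate_quantitative_contrast(
    seed: int,
    n_ions: int = 2000,
    sig_frac_per_diet: float = 0.05,
    near_threshold_frac: float = 0.30,
    effect_size: float = 4.0,
    log_sd: float = 0.3,
    design: StudyDesign | None = None,
    presence_threshold: float = 1000.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Fly-only dataset whose diet signal is purely quantitative.

    Every ion is present in every fly sample, so per-sample
    presence/absence carries no diet information at all: a fraction of
    ions sits near the detection threshold and flickers at random, the
    rest are solidly detected everywhere.  Diet identity lives only in
    the quantitative elevation (``effect_size``-fold) of each diet's
    signature ions.  No generation batch effect is applied: the dataset
    isolates the qualitative-vs-quantitative comparison.
    """
    design = design or StudyDesign(has_controls=False, has_blank=False)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 2)))
    diets = design.diets
    counts = _largest_remainder(
        n_ions,
        np.array([sig_frac_per_diet] * len(diets) + [near_threshold_frac]
                 + [1.0 - sig_frac_per_diet * len(diets) - near_threshold_frac]),
    )
    labels: list[tuple[str, str | None]] = []
    for diet, c in zip(diets, counts[: len(diets)]):
        labels.extend([("signature", diet)] * c)
    labels.extend([("near_threshold", None)] * counts[len(diets)])
    labels.extend([("bulk", None)] * counts[len(diets) + 1])

    classes = np.array([c for c, _ in labels])
    ion_diet = np.array([d if d is not None else "" for _, d in labels])
    base = np.where(
        classes == "near_threshold",
        math.log(1.5 * presence_threshold) + rng.normal(0.0, 0.2, n_ions),
        math.log(5e4) + rng.normal(0.0, 0.8, n_ions),
    )

    rows = []
    for diet in diets:
        for g in design.generations_for(diet):
            for r in range(1, design.fly_reps + 1):
                rows.append((f"fly_{diet}_g{g}_r{r}", "fly", diet, g, r))
    samples = pd.DataFrame(rows, columns=["sample_id", "kind", "diet", "generation", "replicate"])

    areas = np.empty((n_ions, len(samples)))
    log_eff = math.log(effect_size)
    for j, row in samples.iterrows():
        mean = base + log_eff * ((classes == "signature") & (ion_diet == row["diet"]))
        areas[:, j] = np.exp(mean + log_sd * rng.standard_normal(n_ions))

    ion_ids = [f"M{100 + i}.{i % 10}T{i}" for i in range(n_ions)]
    table = FeatureTable(
        areas=pd.DataFrame(areas, index=ion_ids, columns=samples["sample_id"]),
        samples=samples,
    )
    truth = pd.DataFrame(
        {"ion_class": classes, "diet": [d for _, d in labels]}, index=pd.Index(ion_ids, name="ion_id")
    )
    return table, truth
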