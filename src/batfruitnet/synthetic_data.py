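"""Synthetic bat-fruit-like interaction networks with planted structure.

The generator emulates the features of field frugivory matrices that the
analysis pipeline exercises: a handful of modules pairing bat genera
with their preferred plant genera (Artibeus-Ficus, Carollia-Piper,
Sturnira-Solanum), right-skewed degree distributions with a generalist
core, count weights on the scale of fecal-sample tallies, and a mix of
primary/secondary/occasional frugivores in which primary frugivores are
the best-connected animals.

Presence of interaction (i, j) is sampled with probability

    p_ij = 1 - (1 - base)^(s_i * s_j)

where ``base`` is ``p_in`` inside a planted module and ``p_out``
outside, and ``s`` are per-species propensities drawn from a log-normal
with sigma = ln(nestedness_skew); the exponent form keeps p_ij in
[0, 1], reduces exactly to ``base`` for unit propensities, and makes
complete/empty blocks exact at base 1/0.  Conditional on presence, a
weight is drawn from a geometric distribution with the requested mean.
Species left with no interactions are repaired with one forced link to
their highest-propensity partner, deterministically, and the repair is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BatFruitNetError
from .modularity_guilds import Partition, modularity_of_partition
from .netio import InteractionMatrix, SpeciesMeta, binarize

BACKGROUND_BAT_GENERA = ("Glossophaga", "Phyllostomus", "Platyrrhinus", "Anoura", "Micronycteris")
BACKGROUND_PLANT_GENERA = ("Cecropia", "Vismia", "Muntingia", "Maclura", "Acnistus")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: a bat genus paired with its preferred plant genus."""

    bat_genus: str
    plant_genus: str
    n_bats: int
    n_plants: int


DEFAULT_MODULE_PLAN = (
    ModuleSpec("Artibeus", "Ficus", 2, 3),
    ModuleSpec("Carollia", "Piper", 2, 3),
    ModuleSpec("Sturnira", "Solanum", 2, 3),
)


def plan_for_size(n_bats: int, n_plants: int) -> tuple[ModuleSpec, ...]:
    """Scale the three-genus module plan to a network size (about a quarter
    of each side per planted genus, never overflowing the totals)."""
    per_bat = max(1, n_bats // 4)
    per_plant = max(1, n_plants // 4)
    plan = [
        ModuleSpec(s.bat_genus, s.plant_genus, per_bat, per_plant)
        for s in DEFAULT_MODULE_PLAN
    ]
    while sum(s.n_bats for s in plan) > n_bats or sum(s.n_plants for s in plan) > n_plants:
        plan = [
            ModuleSpec(s.bat_genus, s.plant_genus, max(1, s.n_bats - 1), max(1, s.n_plants - 1))
            for s in plan
        ]
        if all(s.n_bats == 1 and s.n_plants == 1 for s in plan):
            break
    return tuple(plan)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-network generator.

    Defaults are calibrated to the published field networks: 6-22 bats,
    6-47 plants, three genus-paired modules, within-module interaction
    probability well above the between-module one, moderately
    heavy-tailed propensities, and counts on the fecal-sample scale.
    """

    n_bats: int = 8
    n_plants: int = 15
    module_plan: tuple[ModuleSpec, ...] | None = None  # None = scale the default plan to size
    p_in: float = 0.7
    p_out: float = 0.08
    weight_mean: float = 4.0
    nestedness_skew: float = 2.5
    frugivory_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)  # primary/secondary/occasional
    primary_boost: float = 3.0
    binary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_plan is None:
            self.module_plan = plan_for_size(self.n_bats, self.n_plants)
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise BatFruitNetError("need 0 <= p_out <= p_in <= 1")
        if sum(s.n_bats for s in self.module_plan) > self.n_bats:
            raise BatFruitNetError("planted bat counts exceed n_bats")
        if sum(s.n_plants for s in self.module_plan) > self.n_plants:
            raise BatFruitNetError("planted plant counts exceed n_plants")
        if abs(sum(self.frugivory_mix) - 1) > 1e-9:
            raise BatFruitNetError("frugivory_mix must sum to 1")
        if self.weight_mean < 1:
            raise BatFruitNetError("weight_mean must be >= 1 (geometric counts)")
        if self.nestedness_skew <= 0:
            raise BatFruitNetError("nestedness_skew must be positive")


@dataclass
class GenerationLog:
    repaired: list[tuple[str, str]] = field(default_factory=list)


def _genus_assignments(cfg: GeneratorConfig) -> tuple[list[str], list[str], list[int], list[int]]:
    """Genera and planted-module index (background = len(plan)) per species."""
    bat_genera: list[str] = []
    bat_module: list[int] = []
    plant_genera: list[str] = []
    plant_module: list[int] = []
    for k, spec in enumerate(cfg.module_plan):
        bat_genera += [spec.bat_genus] * spec.n_bats
        bat_module += [k] * spec.n_bats
        plant_genera += [spec.plant_genus] * spec.n_plants
        plant_module += [k] * spec.n_plants
    bg = len(cfg.module_plan)
    i = 0
    while len(bat_genera) < cfg.n_bats:
        bat_genera.append(BACKGROUND_BAT_GENERA[i % len(BACKGROUND_BAT_GENERA)])
        bat_module.append(bg)
        i += 1
    i = 0
    while len(plant_genera) < cfg.n_plants:
        plant_genera.append(BACKGROUND_PLANT_GENERA[i % len(BACKGROUND_PLANT_GENERA)])
        plant_module.append(bg)
        i += 1
    return bat_genera, plant_genera, bat_module, plant_module


def generate_network(
    cfg: GeneratorConfig,
) -> tuple[InteractionMatrix, dict[str, SpeciesMeta], Partition, GenerationLog]:
    """One synthetic network: matrix, metadata, planted partition, log."""
    rng = np.random.default_rng(cfg.seed)
    bat_genera, plant_genera, bat_module, plant_module = _genus_assignments(cfg)
    bat_ids = tuple(f"{g}_bat{i + 1}" for i, g in enumerate(bat_genera))
    plant_ids = tuple(f"{g}_plant{j + 1}" for j, g in enumerate(plant_genera))

    # frugivory levels: planted-module bats are primary by construction
    # (the planted genera are the specialized frugivore genera); the rest
    # fill up the configured mix.
    levels = []
    n_planted = sum(s.n_bats for s in cfg.module_plan)
    levels += ["primary"] * n_planted
    rest = cfg.n_bats - n_planted
    if rest > 0:
        want_primary = max(0, int(round(cfg.frugivory_mix[0] * cfg.n_bats)) - n_planted)
        pool = ["primary"] * want_primary
        remaining = rest - want_primary
        n_sec = int(round(remaining * cfg.frugivory_mix[1] / max(cfg.frugivory_mix[1] + cfg.frugivory_mix[2], 1e-12)))
        pool += ["secondary"] * n_sec + ["occasional"] * (remaining - n_sec)
        rng.shuffle(pool)
        levels += pool

    sigma = float(np.log(cfg.nestedness_skew))
    s_bat = rng.lognormal(mean=0.0, sigma=sigma, size=cfg.n_bats)
    s_plant = rng.lognormal(mean=0.0, sigma=sigma, size=cfg.n_plants)
    s_bat = s_bat * np.where(np.array(levels) == "primary", cfg.primary_boost, 1.0)
    # normalize to unit geometric mean so p_in keeps its nominal meaning
    s_bat /= np.exp(np.mean(np.log(s_bat)))
    s_plant /= np.exp(np.mean(np.log(s_plant)))

    base = np.where(
        np.equal.outer(np.array(bat_module), np.array(plant_module)), cfg.p_in, cfg.p_out
    )
    exponent = np.outer(s_bat, s_plant)
    prob = 1.0 - np.power(1.0 - base, exponent)
    present = rng.random((cfg.n_bats, cfg.n_plants)) < prob
    weights = np.where(
        present, rng.geometric(p=1.0 / cfg.weight_mean, size=present.shape), 0
    ).astype(float)

    log = GenerationLog()
    # repair: connect isolated species to their highest-propensity partner
    for i in np.flatnonzero(weights.sum(axis=1) == 0):
        j = int(np.argmax(s_plant))
        weights[i, j] = 1.0
        log.repaired.append((bat_ids[i], plant_ids[j]))
    for j in np.flatnonzero(weights.sum(axis=0) == 0):
        i = int(np.argmax(s_bat))
        weights[i, j] = 1.0
        log.repaired.append((bat_ids[i], plant_ids[j]))

    matrix = InteractionMatrix(bat_ids, plant_ids, weights)
    if cfg.binary:
        matrix = binarize(matrix)

    meta: dict[str, SpeciesMeta] = {}
    for i, b in enumerate(bat_ids):
        meta[b] = SpeciesMeta(species_id=b, side="animal", genus=bat_genera[i], frugivory_level=levels[i])
    for j, p in enumerate(plant_ids):
        meta[p] = SpeciesMeta(species_id=p, side="plant", genus=plant_genera[j], frugivory_level="not_applicable")

    assignment = {b: bat_module[i] for i, b in enumerate(bat_ids)}
    assignment.update({p: plant_module[j] for j, p in enumerate(plant_ids)})
    planted = Partition(
        assignment=assignment,
        m_value=modularity_of_partition(matrix, assignment),
        n_modules=len(set(assignment.values())),
    )
    return matrix, meta, planted, log


# (n_bats, n_plants) of the nine published field networks, smallest 6 x 6,
# largest 22 x 47; the largest is presence/absence only.
FIELD_NETWORK_SIZES: tuple[tuple[int, int], ...] = (
    (8, 15),
    (6, 14),
    (11, 26),
    (7, 12),
    (22, 47),
    (14, 36),
    (7, 22),
    (7, 11),
    (6, 6),
)


def generate_suite(
    sizes: tuple[tuple[int, int], ...] = FIELD_NETWORK_SIZES,
    seed: int = 0,
    binary_index: int | None = None,
    **overrides,
) -> list[tuple[InteractionMatrix, dict[str, SpeciesMeta], Partition]]:
    """A suite of synthetic networks at the field-study sizes.

    One network (by default the largest, matching the field suite's
    single presence/absence dataset) is generated binary-only so the
    H2'-not-computable path is exercised.
    """
    if binary_index is None:
        binary_index = max(range(len(sizes)), key=lambda k: sizes[k][0] + sizes[k][1])
    seq = np.random.SeedSequence(seed)
    out = []
    for k, ((n_bats, n_plants), child) in enumerate(zip(sizes, seq.spawn(len(sizes)))):
        cfg = GeneratorConfig(
            n_bats=n_bats,
            n_plants=n_plants,
            module_plan=plan_for_size(n_bats, n_plants),
            binary=(k == binary_index),
            seed=int(child.generate_state(1)[0] % (2**31)),
            **overrides,
        )
        matrix, meta, planted, _ = generate_network(cfg)
        out.append((matrix, meta, planted))
    return out
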