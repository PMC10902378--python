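"""Seeded synthetic sequence-activity landscapes and assay data.

This module generates everything the downstream pipeline consumes, so
the whole analysis is testable end to end without any external data:

* additive-plus-sparse-epistasis activity landscapes over a handful of
  combinatorially mutated sites (parent-anchored: the parent variant's
  noise-free activity is the landscape intercept, on the same
  dimensionless fold-over-parent scale the plate assay produces);
* plate-organized screens — each well gets a kinetic slope (dA/min)
  subject to a multiplicative log-normal per-plate batch factor and
  additive measurement noise, plus a 17-point absorbance trace
  (0–80 min at 5-min spacing) consistent with that slope, with a floor
  once the simulated cofactor budget is exhausted;
* Michaelis–Menten initial-rate datasets with relative (CV) noise.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import ActivityRecord, KineticTrace
from .encoding import AAPropertyTable, default_property_table
from .variants import ProteinVariant, variant_from_residues

#: Trace time grid: recorded every 5 min for 80 min (17 samples).
TRACE_TIMES = np.arange(0.0, 80.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class SyntheticLandscape:
    """A parent-anchored additive + pairwise-epistatic activity landscape.

    ``site_effects[(site, residue)]`` is the additive contribution of
    carrying ``residue`` at ``site``; the parent residue at every site
    has effect 0, so the parent's true activity equals ``intercept``.
    ``epistasis_terms`` holds sparse pairwise interaction terms keyed
    with strictly increasing site order, restricted to non-parent
    residues at both sites.
    """

    sites: tuple[int, ...]
    alphabets: dict[int, str]
    parent_residues: dict[int, str]
    intercept: float
    site_effects: dict[tuple[int, str], float]
    epistasis_terms: dict[tuple[tuple[int, str], tuple[int, str]], float]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for site in self.sites:
            parent = self.parent_residues[site]
            if parent not in self.alphabets[site]:
                raise ValueError(f"parent residue {parent!r} not in alphabet of site {site}")
            if abs(self.site_effects.get((site, parent), 0.0)) > 0:
                raise ValueError(f"parent residue at site {site} must have zero effect")
        for (site, res) in self.site_effects:
            if site not in self.alphabets or res not in self.alphabets[site]:
                raise ValueError(f"site effect references unknown residue {res!r} at site {site}")
        for (a, b) in self.epistasis_terms:
            if not a[0] < b[0]:
                raise ValueError(f"epistasis key {(a, b)} not in increasing site order")
            for site, res in (a, b):
                if site not in self.alphabets or res not in self.alphabets[site]:
                    raise ValueError(
                        f"epistasis term references unknown residue {res!r} at site {site}"
                    )

    def variant(self, residues: Mapping[int, str], parent: str = "WT") -> ProteinVariant:
        """Variant from a site -> residue assignment over landscape sites."""
        return variant_from_residues(residues, self.parent_residues, parent=parent)


def enumerate_epistasis_pairs(
    sites: Sequence[int],
    alphabets: Mapping[int, str],
    parent_residues: Mapping[int, str],
) -> list[tuple[tuple[int, str], tuple[int, str]]]:
    """All cross-site pairs of non-parent residues, sites ascending.

    Restricting pairs to non-parent residues keeps the parameterization
    parent-anchored: parent and single-substitution variants are
    untouched by interaction terms.
    """
    pairs = []
    ordered = sorted(sites)
    for i, j in itertools.combinations(range(len(ordered)), 2):
        si, sj = ordered[i], ordered[j]
        for ri in alphabets[si]:
            if ri == parent_residues[si]:
                continue
            for rj in alphabets[sj]:
                if rj == parent_residues[sj]:
                    continue
                pairs.append(((si, ri), (sj, rj)))
    return pairs


def make_landscape(
    sites: Sequence[int],
    alphabets: str | Sequence[str] | Mapping[int, str],
    epistasis_fraction: float = 0.0,
    effect_sd: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 1.0,
    parent_residues: Mapping[int, str] | None = None,
    epistasis_sd: float | None = None,
    effect_model: str = "free",
    property_table: AAPropertyTable | None = None,
) -> SyntheticLandscape:
    """Draw a seeded random landscape.

    ``epistasis_fraction`` is the proportion of enumerable cross-site
    residue pairs given a nonzero interaction term.  Two additive effect
    models are supported:

    * ``"free"`` — i.i.d. Normal(0, effect_sd) effect per non-parent
      residue;
    * ``"descriptor_linear"`` — each site's effects are a random linear
      functional of the standardized physicochemical descriptor vectors
      (scaled so non-parent effects have SD ``effect_sd``), which makes
      the true activity an exactly linear function of the concatenated
      descriptor encoding.

    Interaction terms are Normal(0, epistasis_sd); by default half the
    main-effect scale, reflecting that epistasis is typically weaker
    than main effects.
    """
    sites = [int(s) for s in sites]
    if not 1 <= len(sites) <= 10:
        raise ValueError(f"number of sites must be in [1, 10], got {len(sites)}")
    if len(set(sites)) != len(sites):
        dup = next(s for s in sites if sites.count(s) > 1)
        raise ValueError(f"duplicate site {dup}")
    if not 0 <= epistasis_fraction <= 1:
        raise ValueError("epistasis_fraction must be in [0, 1]")
    if effect_model not in ("free", "descriptor_linear"):
        raise ValueError(f"unknown effect model {effect_model!r}")

    if isinstance(alphabets, Mapping):
        alpha = {s: str(alphabets[s]) for s in sites}
    elif isinstance(alphabets, str):
        alpha = {s: alphabets for s in sites}
    else:
        if len(alphabets) != len(sites):
            raise ValueError("one alphabet per site required")
        alpha = {s: str(a) for s, a in zip(sites, alphabets)}
    for s, a in alpha.items():
        if len(a) == 0:
            raise ValueError(f"empty alphabet at site {s}")

    if parent_residues is None:
        parents = {s: alpha[s][0] for s in sites}
    else:
        parents = {s: parent_residues[s] for s in sites}

    rng = np.random.default_rng(seed)
    site_effects: dict[tuple[int, str], float] = {}
    if effect_model == "free":
        for s in sorted(sites):
            for res in alpha[s]:
                site_effects[(s, res)] = (
                    0.0 if res == parents[s] else float(rng.normal(0.0, effect_sd))
                )
    else:
        table = property_table if property_table is not None else default_property_table()
        for s in sorted(sites):
            w = rng.normal(0.0, 1.0, size=table.n_properties)
            raw = {res: float(w @ table.vector(res)) for res in alpha[s]}
            anchored = {res: raw[res] - raw[parents[s]] for res in alpha[s]}
            non_parent = [v for r, v in anchored.items() if r != parents[s]]
            scale = float(np.std(non_parent)) if len(non_parent) > 1 else 1.0
            scale = scale if scale > 0 else 1.0
            for res in alpha[s]:
                site_effects[(s, res)] = anchored[res] * effect_sd / scale

    pairs = enumerate_epistasis_pairs(sites, alpha, parents)
    n_terms = int(round(epistasis_fraction * len(pairs)))
    epi_sd = epistasis_sd if epistasis_sd is not None else 0.5 * effect_sd
    epistasis: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
    if n_terms > 0:
        chosen = rng.choice(len(pairs), size=n_terms, replace=False)
        for idx in sorted(chosen):
            epistasis[pairs[idx]] = float(rng.normal(0.0, epi_sd))

    return SyntheticLandscape(
        sites=tuple(sorted(sites)),
        alphabets=alpha,
        parent_residues=parents,
        intercept=float(intercept),
        site_effects=site_effects,
        epistasis_terms=epistasis,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def _residues_of(landscape: SyntheticLandscape, variant) -> dict[int, str]:
    if isinstance(variant, ProteinVariant):
        residues = dict(variant.residue_map)
    else:
        residues = {int(k): v for k, v in dict(variant).items()}
    for site, res in residues.items():
        if site not in landscape.alphabets:
            raise ValueError(f"substitution at site {site} outside the landscape sites")
        if res not in landscape.alphabets[site]:
            raise ValueError(f"residue {res!r} not allowed at site {site}")
    full = dict(landscape.parent_residues)
    full.update(residues)
    return full


def true_activity(landscape: SyntheticLandscape, variant) -> float:
    """Noise-free activity: intercept + additive effects + pair terms."""
    residues = _residues_of(landscape, variant)
    total = landscape.intercept
    for site in landscape.sites:
        total += landscape.site_effects.get((site, residues[site]), 0.0)
    for (a, b), effect in landscape.epistasis_terms.items():
        if residues[a[0]] == a[1] and residues[b[0]] == b[1]:
            total += effect
    return float(total)


def random_variants(
    landscape: SyntheticLandscape,
    n: int,
    seed: int,
    parent: str = "WT",
    unique: bool = True,
) -> list[ProteinVariant]:
    """Sample variants uniformly over the landscape's combinatorial space."""
    rng = np.random.default_rng(seed)
    space = int(np.prod([len(landscape.alphabets[s]) for s in landscape.sites]))
    if unique and n > space:
        raise ValueError(f"cannot draw {n} unique variants from a space of {space}")
    seen: set[tuple[str, ...]] = set()
    out: list[ProteinVariant] = []
    while len(out) < n:
        combo = tuple(
            landscape.alphabets[s][rng.integers(len(landscape.alphabets[s]))]
            for s in landscape.sites
        )
        if unique:
            if combo in seen:
                continue
            seen.add(combo)
        out.append(landscape.variant(dict(zip(landscape.sites, combo)), parent=parent))
    return out


def enumerate_variants(landscape: SyntheticLandscape, parent: str = "WT"):
    """All variants of the landscape space, sites ascending, alphabet order."""
    for combo in itertools.product(*(landscape.alphabets[s] for s in landscape.sites)):
        yield landscape.variant(dict(zip(landscape.sites, combo)), parent=parent)


@dataclass(frozen=True)
class PlateLayout:
    """Plate geometry and control layout for a simulated screen.

    The default of 4 parent-control wells per 96-well plate is a stated
    convention of the generator (real screens vary); at least one parent
    well is required for plate normalization to be defined.
    """

    n_wells: int = 96
    wt_wells_per_plate: int = 4
    plate_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.wt_wells_per_plate < 1:
            raise ValueError("plate normalization requires >= 1 parent well per plate")
        if self.n_wells < self.wt_wells_per_plate:
            raise ValueError("n_wells must be >= wt_wells_per_plate")
        if self.plate_effect_sd < 0:
            raise ValueError("plate_effect_sd must be >= 0")


def _well_names(n_wells: int) -> list[str]:
    if n_wells == 96:
        return [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]
    return [f"W{i + 1:03d}" for i in range(n_wells)]


def simulate_screen(
    landscape: SyntheticLandscape,
    variants: Sequence[ProteinVariant],
    layout: PlateLayout,
    seed: int,
    parent_name: str = "WT",
    slope_scale: float = 0.008,
    initial_absorbance: float = 1.0,
    absorbance_budget: float = 1.0,
) -> tuple[list[ActivityRecord], list[KineticTrace]]:
    """Assign variants and parent controls to plates and read them out.

    Each plate draws a multiplicative log-normal batch factor
    exp(Normal(0, plate_effect_sd)); each well's slope is

        plate_factor * max(true_activity + noise, 0) * slope_scale

    in dA/min (an inactive enzyme cannot un-consume cofactor, so
    negative draws clip to zero).  The emitted trace declines linearly
    at that slope from ``initial_absorbance`` until the absorbance
    budget (simulated cofactor) is exhausted, then floors.
    """
    rng = np.random.default_rng(seed)
    wells = _well_names(layout.n_wells)
    per_plate = layout.n_wells - layout.wt_wells_per_plate
    if per_plate < 1:
        raise ValueError("layout leaves no wells for variants")
    n_plates = max(1, -(-len(variants) // per_plate))

    records: list[ActivityRecord] = []
    traces: list[KineticTrace] = []
    floor = initial_absorbance - absorbance_budget
    parent = ProteinVariant(parent=parent_name, substitutions=())
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        plate_factor = float(np.exp(rng.normal(0.0, layout.plate_effect_sd)))
        chunk = variants[p * per_plate : (p + 1) * per_plate]
        occupants = [parent] * layout.wt_wells_per_plate + list(chunk)
        for well, var in zip(wells, occupants):
            activity = true_activity(landscape, var)
            noise = float(rng.normal(0.0, landscape.noise_sd)) if landscape.noise_sd else 0.0
            slope = plate_factor * max(activity + noise, 0.0) * slope_scale
            absorbance = np.maximum(initial_absorbance - slope * TRACE_TIMES, floor)
            records.append(
                ActivityRecord(
                    variant_name=var.name, plate=plate_id, well=well, slope=slope
                )
            )
            traces.append(
                KineticTrace(
                    times=TRACE_TIMES.copy(),
                    absorbance=absorbance,
                    well=well,
                    plate=plate_id,
                    variant_name=var.name,
                )
            )
    return records, traces


def default_substrate_grid(km: float, n: int = 8) -> np.ndarray:
    """Log-spaced substrate design from km/10 to 10*km (identifiable)."""
    return np.geomspace(km / 10.0, 10.0 * km, n)


def simulate_mm_dataset(
    kcat: float,
    km: float,
    enzyme_conc: float,
    substrate_grid: Sequence[float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis–Menten initial rates with relative Gaussian noise.

    Units follow the assay convention: kcat in 1/min, km and enzyme
    concentration in uM, rates in uM/min.  Each observed rate is the
    true rate times (1 + eps), eps ~ Normal(0, noise_cv).
    """
    if kcat <= 0 or km <= 0 or enzyme_conc <= 0:
        raise ValueError("kcat, km and enzyme_conc must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    grid = (
        default_substrate_grid(km)
        if substrate_grid is None
        else np.asarray(substrate_grid, dtype=float)
    )
    if grid.size == 0:
        raise ValueError("substrate grid is empty")
    if np.any(grid < 0):
        raise ValueError("substrate concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    v = kcat * enzyme_conc * grid / (km + grid)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=grid.size))
    return pd.DataFrame({"substrate_uM": grid, "rate_uM_per_min": v})
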