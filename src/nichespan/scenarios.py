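"""Preset synthetic study conditions.

These constructors freeze the simulation conditions used throughout the
package's documentation and validation: layered band slices (cortical
layer analogue), a five-slice set with a rare immune-aggregate domain
present in four slices (tertiary-lymphoid-structure analogue), condition
groups of slices with group-specific domain mixes, a spatial-vs-global
confound pair, separated disc domains for resolution-selection studies,
and a homogeneous single-domain slice.  Domains are drawn spatially
separated (margins exceeding the niche reach) with strongly distinct
compositions — the well-separated regime in which domain recovery is
exact and deviations are attributable to the injected perturbations.
"""

from __future__ import annotations

import numpy as np

from .simulate import Band, Disc, DomainSpec, SimulationConfig

__all__ = [
    "banded_slices",
    "tls_multislice",
    "condition_groups",
    "confound_pair",
    "separated_discs",
    "homogeneous_slice",
]

#: cell types of the immune/tumor scenario; the first three are the
#: lymphoid types that enrich the rare domain
TLS_TYPES = ("B_cell", "CD8_T", "T_helper", "Tumor", "Fibroblast", "Endothelial")


def banded_slices(
    n_bands: int,
    seed: int,
    n_obs_per_band: int = 100,
    label_noise_rate: float = 0.0,
    n_slices: int = 1,
) -> SimulationConfig:
    """Horizontal bands with pairwise disjoint two-type compositions.

    Band i draws its cells from types ``t{2i}`` (60%) and ``t{2i+1}``
    (40%); bands are 40 units tall with 60-unit gaps, well beyond the
    reach of a k=30 niche at the default density.
    """
    t_count = 2 * n_bands
    cell_types = tuple(f"t{j}" for j in range(t_count))
    domains = []
    for i in range(n_bands):
        comp = np.zeros(t_count)
        comp[2 * i] = 0.6
        comp[2 * i + 1] = 0.4
        domains.append(
            DomainSpec(
                f"band{i + 1}", comp, Band(0, 100, i * 100, i * 100 + 40),
                n_obs_per_band,
            )
        )
    return SimulationConfig(
        cell_types=cell_types,
        domains=tuple(domains),
        seed=seed,
        n_slices=n_slices,
        label_noise_rate=label_noise_rate,
    )


def tls_multislice(seed: int, n_slices: int = 5, tls_in=(0, 1, 2, 3)) -> SimulationConfig:
    """Five slices with tumor and stroma bands everywhere and a small
    B/T-cell-enriched disc domain present only in ``tls_in`` slices."""
    tumor = DomainSpec(
        "tumor", np.array([0.02, 0.03, 0.0, 0.75, 0.15, 0.05]), Band(0, 100, 0, 40), 150
    )
    stroma = DomainSpec(
        "stroma", np.array([0.0, 0.05, 0.05, 0.05, 0.55, 0.30]), Band(0, 100, 80, 120), 150
    )
    tls = DomainSpec(
        "tls", np.array([0.45, 0.30, 0.15, 0.02, 0.05, 0.03]), Disc(50, 200, 15), 60
    )
    return SimulationConfig(
        cell_types=TLS_TYPES,
        domains=(tumor, stroma),
        seed=seed,
        n_slices=n_slices,
        rare_domain=tls,
        rare_domain_in=tuple(tls_in),
    )


def condition_groups(
    seed: int, n_groups: int = 3, slices_per_group: int = 3
) -> tuple[SimulationConfig, np.ndarray]:
    """Slices in condition groups with group-specific domain mixes.

    Three shared band domains appear in every slice, but each group
    rescales their sizes differently (the spatial-domain composition is
    the group signature).  Returns the configuration and the true group
    label per slice.
    """
    cell_types = tuple("ABCDEF")
    domains = tuple(
        DomainSpec(
            f"d{i + 1}",
            np.roll(np.array([0.7, 0.3, 0, 0, 0, 0]), 2 * i),
            Band(0, 100, i * 100, i * 100 + 40),
            120,
        )
        for i in range(3)
    )
    base_scales = [(1.5, 0.5, 0.25), (0.25, 1.5, 0.5), (0.5, 0.25, 1.5)]
    scales, groups = [], []
    for g in range(n_groups):
        for _ in range(slices_per_group):
            scales.append(base_scales[g % len(base_scales)])
            groups.append(g + 1)
    config = SimulationConfig(
        cell_types=cell_types,
        domains=domains,
        seed=seed,
        n_slices=n_groups * slices_per_group,
        slice_domain_scale=tuple(scales),
    )
    return config, np.array(groups)


def confound_pair(seed: int, slices_per_group: int = 3) -> tuple[SimulationConfig, np.ndarray]:
    """Equal global cell-type mix, different spatial arrangement.

    Group 1 slices segregate types A and B into two pure bands; group 2
    slices mix them uniformly in one band.  Every slice has the same
    50/50 global composition, so only spatial-domain composition can
    separate the groups.
    """
    pure_a = DomainSpec("pureA", np.array([1.0, 0.0]), Band(0, 100, 0, 40), 150)
    pure_b = DomainSpec("pureB", np.array([0.0, 1.0]), Band(0, 100, 80, 120), 150)
    mixed = DomainSpec("mixed", np.array([0.5, 0.5]), Band(0, 100, 160, 200), 300)
    scales = [(1, 1, 0)] * slices_per_group + [(0, 0, 1)] * slices_per_group
    config = SimulationConfig(
        cell_types=("A", "B"),
        domains=(pure_a, pure_b, mixed),
        seed=seed,
        n_slices=2 * slices_per_group,
        slice_domain_scale=tuple(scales),
    )
    groups = np.array([1] * slices_per_group + [2] * slices_per_group)
    return config, groups


def separated_discs(
    n_domains: int, seed: int, n_obs_per_domain: int = 60
) -> SimulationConfig:
    """3-6+ well-separated disc domains with overlapping-support
    compositions (70/30 over adjacent types), for resolution-selection
    studies."""
    t_count = max(8, n_domains + 1)
    cell_types = tuple(f"t{j}" for j in range(t_count))
    domains = []
    for i in range(n_domains):
        comp = np.zeros(t_count)
        comp[i] = 0.7
        comp[(i + 1) % t_count] = 0.3
        domains.append(
            DomainSpec(
                f"d{i + 1}", comp, Disc((i % 3) * 300, (i // 3) * 300, 40),
                n_obs_per_domain,
            )
        )
    return SimulationConfig(cell_types=cell_types, domains=tuple(domains), seed=seed)


def homogeneous_slice(seed: int, n_obs: int = 400) -> SimulationConfig:
    """One spatially uniform domain (no structure to detect)."""
    return SimulationConfig(
        cell_types=("A", "B", "C"),
        domains=(
            DomainSpec("only", np.array([0.5, 0.3, 0.2]), Band(0, 100, 0, 100), n_obs),
        ),
        seed=seed,
    )
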