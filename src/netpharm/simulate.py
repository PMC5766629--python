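"""Seeded generators for synthetic PPI networks and two-class NMR spectra.

These emulate the statistical structure the analysis stages assume, so
the whole pipeline can be exercised end to end without any database
downloads or raw spectra:

* :func:`gen_ppi` plants named hub targets of chosen degree inside a
  random background interactome, returning the graph together with the
  designed importance ordering of the hubs;
* :func:`gen_spectra` renders two groups of spectra as sums of
  Lorentzian resonances (the natural solution-NMR line shape) with
  class-dependent concentration ratios plus additive Gaussian noise
  floored at zero, returning the ground-truth list of discriminating
  metabolites.

Both are pure functions of their spec (seed included): the same spec
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .network import Network
from .nmr import SpectrumSet

__all__ = [
    "PPISimSpec",
    "SpectraSimSpec",
    "MetabolitePeak",
    "gen_ppi",
    "gen_spectra",
    "default_metabolite_panel",
]


# ---------------------------------------------------------------------
# PPI graphs with planted hubs
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PPISimSpec:
    """Spec for a background interactome with planted hub targets.

    ``planted_hubs`` lists (target ID, desired degree) pairs; each hub
    is wired to that many distinct background proteins.  Background
    edges follow preferential attachment (scale-free-ish, the shape of
    real PPI networks) or uniform random pairing.
    """

    n_background: int = 300
    planted_hubs: tuple[tuple[str, int], ...] = (
        ("HUB1", 60),
        ("HUB2", 30),
        ("HUB3", 15),
    )
    attachment: Literal["preferential", "uniform"] = "preferential"
    background_m: int = 3
    seed: int = 0


def gen_ppi(spec: PPISimSpec) -> tuple[Network, list[str]]:
    """Generate the planted-hub PPI network.

    Returns the network and the hub IDs ordered by designed importance
    (descending planted degree; this is the expected ordering of their
    topology-based R ranks).
    """
    for name, deg in spec.planted_hubs:
        if deg >= spec.n_background:
            raise ValueError(
                f"infeasible degree {deg} for hub {name!r}: only "
                f"{spec.n_background} background nodes available"
            )
    if spec.attachment == "preferential":
        g = nx.barabasi_albert_graph(
            spec.n_background, spec.background_m, seed=spec.seed
        )
    elif spec.attachment == "uniform":
        g = nx.gnm_random_graph(
            spec.n_background,
            spec.background_m * spec.n_background,
            seed=spec.seed,
        )
    else:
        raise ValueError(f"unknown attachment {spec.attachment!r}")
    mapping = {i: f"P{i:04d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)

    rng = np.random.default_rng(spec.seed)
    background = sorted(g.nodes)
    edges = list(g.edges)
    for name, deg in spec.planted_hubs:
        partners = rng.choice(len(background), size=deg, replace=False)
        edges.extend((name, background[j]) for j in partners)
    net = Network.from_edges(edges)
    for name, _ in spec.planted_hubs:
        net.set_role(name, "target")
    ranking = [
        name
        for name, _ in sorted(spec.planted_hubs, key=lambda h: (-h[1], h[0]))
    ]
    return net, ranking


# ---------------------------------------------------------------------
# two-class NMR spectra
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class MetabolitePeak:
    """One simulated metabolite: resonance positions (ppm), per-resonance
    multiplicity weights, base concentration in the control group, and
    the treated/control concentration ratio (1.0 = not discriminating)."""

    name: str
    shifts: tuple[float, ...]
    weights: tuple[float, ...]
    base_concentration: float
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if len(self.shifts) != len(self.weights):
            raise ValueError(f"{self.name}: shifts and weights differ in length")
        if not all(0.50 <= s < 9.00 for s in self.shifts):
            raise ValueError(f"{self.name}: shifts must lie in [0.50, 9.00)")
        if self.ratio <= 0 or self.base_concentration <= 0:
            raise ValueError(f"{self.name}: concentrations and ratio must be > 0")


def default_metabolite_panel() -> tuple[MetabolitePeak, ...]:
    """A small panel of common cell-extract metabolites with resonances
    at their textbook chemical shifts.  Effect directions and magnitudes
    echo what an effective treatment typically does to glycolytic and
    amino-acid metabolism; four panel members are unchanged (ratio 1)
    and serve as negative controls."""
    return (
        # large, unchanged pools dominate total intensity, as in real
        # cell extracts; keeps row-sum normalization from distorting the
        # apparent fold changes of the minor components
        MetabolitePeak("lactate", (1.33, 4.11), (1.0, 0.3), 20.0, 1.0),
        MetabolitePeak("beta-glucose", (4.65, 3.25), (1.0, 0.8), 8.0, 1.0),
        MetabolitePeak("phenylalanine", (7.33, 7.42), (1.0, 1.0), 0.5, 1.0),
        MetabolitePeak("formate", (8.46,), (1.0,), 0.4, 1.0),
        # discriminating minor components (up and down in treated)
        MetabolitePeak("leucine", (0.96, 1.70), (1.0, 0.5), 0.5, 4.0),
        MetabolitePeak("valine", (0.99, 1.04), (1.0, 1.0), 0.4, 5.4),
        MetabolitePeak("acetate", (1.92,), (1.0,), 0.5, 4.8),
        MetabolitePeak("pyruvate", (2.37,), (1.0,), 0.5, 4.9),
        MetabolitePeak("succinate", (2.41,), (1.0,), 0.4, 2.2),
        MetabolitePeak("glutamate", (2.05, 2.35), (1.0, 0.8), 1.0, 1 / 3.0),
        MetabolitePeak("glutamine", (2.14, 2.45), (1.0, 0.8), 0.5, 1.5),
        MetabolitePeak("creatine", (3.04, 3.93), (1.0, 0.7), 0.5, 1 / 2.6),
        MetabolitePeak("glycine", (3.56,), (1.0,), 0.6, 1 / 2.9),
        MetabolitePeak("glycerol", (3.65,), (1.0,), 0.4, 2.3),
        MetabolitePeak("tyrosine", (6.90, 7.19), (1.0, 1.0), 0.3, 3.7),
        MetabolitePeak("hypoxanthine", (8.19, 8.21), (1.0, 1.0), 0.3, 1 / 3.2),
    )


@dataclass(frozen=True)
class SpectraSimSpec:
    """Spec for two-class synthetic spectra.

    Defaults emulate the study design the pipeline targets: six
    biological replicates per group, Lorentzian half-width 0.002 ppm on
    a 0.001-ppm grid over [0.50, 9.00), additive Gaussian noise.
    """

    n_per_group: int = 6
    metabolites: tuple[MetabolitePeak, ...] = field(
        default_factory=default_metabolite_panel
    )
    peak_width: float = 0.002
    noise_sd: float = 0.02
    grid_step: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        names = [m.name for m in self.metabolites]
        if len(names) != len(set(names)):
            raise ValueError("duplicate metabolite names in spec")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")


def lorentzian(ppm: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-height Lorentzian line: gamma^2 / ((x - x0)^2 + gamma^2)."""
    return hwhm**2 / ((ppm - center) ** 2 + hwhm**2)


def gen_spectra(spec: SpectraSimSpec) -> tuple[SpectrumSet, list[str]]:
    """Render the two-class spectrum set.

    Each sample's spectrum is the concentration-weighted sum of its
    metabolites' Lorentzian resonances evaluated on the grid, plus
    i.i.d. Gaussian noise, floored at zero.  Returns the spectra
    (control samples first, then treated) and the ground-truth list of
    discriminating metabolites (those with ratio != 1).
    """
    grid = np.round(np.arange(0.50, 9.00, spec.grid_step), 6)[::-1]  # descending
    rng = np.random.default_rng(spec.seed)

    shapes = {
        m.name: sum(
            w * lorentzian(grid, s, spec.peak_width)
            for s, w in zip(m.shifts, m.weights)
        )
        for m in spec.metabolites
    }
    n = spec.n_per_group
    sample_ids = [f"control_{i + 1}" for i in range(n)] + [
        f"treated_{i + 1}" for i in range(n)
    ]
    groups = np.array(["control"] * n + ["treated"] * n)
    intensities = np.zeros((2 * n, grid.size))
    for m in spec.metabolites:
        conc = np.where(groups == "treated",
                        m.base_concentration * m.ratio,
                        m.base_concentration)
        intensities += conc[:, None] * shapes[m.name][None, :]
    if spec.noise_sd > 0:
        intensities += rng.normal(0.0, spec.noise_sd, size=intensities.shape)
        np.clip(intensities, 0.0, None, out=intensities)

    truth = [m.name for m in spec.metabolites if m.ratio != 1.0]
    return (
        SpectrumSet(
            ppm=grid, intensities=intensities,
            sample_ids=sample_ids, groups=groups,
        ),
        truth,
    )


def assignments_from_spec(spec: SpectraSimSpec) -> dict[str, tuple[float, ...]]:
    """Metabolite -> chemical shift assignment table implied by a spec
    (the input :func:`netpharm.nmr.call_differential` expects)."""
    return {m.name: m.shifts for m in spec.metabolites}
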