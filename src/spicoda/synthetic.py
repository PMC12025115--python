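"""Seeded generators for synthetic spicule compositions and Raman spectra.

The compositional generator draws additive logistic-normal clusters:
ILR coordinates are sampled from a spherical normal centred at the ILR
image of the cluster center, with per-coordinate variance
``total_variance / (D - 1)`` so the expected total metric variance
equals the specification. This is the minimal generative model
consistent with analysing the data in Aitchison geometry; its single
spread parameter maps directly onto the published per-cluster total
variances.

Default scenarios encode the study conditions for *Onchidoris muricata*
spicules: three section clusters (SC I-III, n = 14/41/45, total
variances 0.1063/0.2553/0.2567) and four fracture clusters (FC I-IV,
n = 19/27/19/40, total variances 0.7958/0.7080/0.3288/0.9920), on the
amalgamated parts (C, O, Ca, Mg, Traces). Seven-element specs
additionally zero the trace elements (Cl, F, P) with per-element
non-detection probabilities, reproducing patterns such as phosphorus
being present in all SC I spicules but absent from SC II and SC III.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CompositionTable, CompositionError, close_vector
from .raman import Spectrum
from .transforms import ilr_inv, make_sbp_basis
import numpy.polynomial.polynomial as npoly

__all__ = [
    "ClusterSpec",
    "generate_clusters",
    "generate_raman_spectrum",
    "section_cluster_specs",
    "fracture_cluster_specs",
    "AMALGAMATED_PARTS",
    "SECTION_CENTERS",
    "FRACTURE_CENTERS",
    "CALCITE_BANDS",
]

#: Part order of the amalgamated composition tables.
AMALGAMATED_PARTS = ("C", "O", "Ca", "Mg", "Traces")

#: Published section-cluster centers (percent) and spreads, by cluster:
#: (center over AMALGAMATED_PARTS, total variance, n).
SECTION_CENTERS: dict[str, tuple[tuple[float, ...], float, int]] = {
    "SC I": ((20.07, 46.05, 19.80, 1.60, 12.48), 0.1063, 14),
    "SC II": ((9.47, 61.96, 21.72, 3.94, 2.90), 0.2553, 41),
    "SC III": ((8.06, 53.49, 33.82, 2.88, 1.74), 0.2567, 45),
}

#: Published fracture-cluster centers (percent) and spreads.
FRACTURE_CENTERS: dict[str, tuple[tuple[float, ...], float, int]] = {
    "FC I": ((14.79, 29.69, 36.53, 1.26, 17.72), 0.7958, 19),
    "FC II": ((11.58, 53.55, 29.59, 3.20, 2.07), 0.7080, 27),
    "FC III": ((10.46, 62.46, 16.75, 5.32, 5.00), 0.3288, 19),
    "FC IV": ((17.31, 53.32, 15.91, 1.91, 11.54), 0.9920, 40),
}

#: Characteristic Raman bands of (magnesian) calcite used by the
#: synthetic spectrum scenarios: lattice mode, nu4 in-plane bend, nu1
#: symmetric carbonate stretch (center cm^-1, FWHM cm^-1, rel. amplitude).
CALCITE_BANDS: tuple[tuple[float, float, float], ...] = (
    (282.0, 12.0, 0.35),
    (712.0, 10.0, 0.2),
    (1087.0, 8.0, 1.0),
)


@dataclasses.dataclass(frozen=True)
class ClusterSpec:
    """Specification of one synthetic cluster.

    ``center`` is a positive composition (percent, closed to 100 on
    construction) over ``parts``; ``total_variance`` the target total
    metric variance; ``trace_zero_prob`` optional per-part non-detection
    probabilities (only meaningful for unamalgamated trace elements).
    """

    name: str
    parts: tuple[str, ...]
    center: tuple[float, ...]
    total_variance: float
    n: int
    trace_zero_prob: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.center) != len(self.parts):
            raise CompositionError("center length must match parts")
        c = np.asarray(self.center, dtype=float)
        if np.any(c <= 0):
            raise CompositionError(f"spec {self.name!r}: center must be positive")
        if self.total_variance <= 0:
            raise CompositionError(f"spec {self.name!r}: total_variance must be > 0")
        if self.n < 1:
            raise CompositionError(f"spec {self.name!r}: n must be >= 1")
        for p, q in self.trace_zero_prob.items():
            if p not in self.parts:
                raise CompositionError(f"spec {self.name!r}: unknown part {p!r}")
            if not 0 <= q <= 1:
                raise CompositionError(
                    f"spec {self.name!r}: probability for {p!r} outside [0, 1]"
                )
        object.__setattr__(self, "center", tuple(close_vector(c, 100.0)))


def section_cluster_specs() -> list[ClusterSpec]:
    """The three section clusters at their published centers and sizes."""
    return [
        ClusterSpec(name, AMALGAMATED_PARTS, ctr, tv, n)
        for name, (ctr, tv, n) in SECTION_CENTERS.items()
    ]


def fracture_cluster_specs() -> list[ClusterSpec]:
    """The four fracture clusters at their published centers and sizes."""
    return [
        ClusterSpec(name, AMALGAMATED_PARTS, ctr, tv, n)
        for name, (ctr, tv, n) in FRACTURE_CENTERS.items()
    ]


def generate_clusters(
    specs: Sequence[ClusterSpec],
    seed: int,
    prep: str | None = None,
) -> tuple[CompositionTable, pd.Series]:
    """Draw a labelled composition table from cluster specifications.

    Samples are generated spec by spec in the given order from a single
    seeded stream, so output is bit-reproducible. Returns the table
    (rows closed to 100) and the true-label Series. Trace elements with
    a stated non-detection probability are zeroed after sampling and the
    remaining parts re-closed, exercising the downstream zero-handling
    path.
    """
    if not specs:
        raise CompositionError("no cluster specs given")
    parts = specs[0].parts
    for s in specs:
        if s.parts != parts:
            raise CompositionError("all specs must share the same parts")
    rng = np.random.default_rng(seed)
    basis = make_sbp_basis(parts)
    D = len(parts)
    rows, ids, labels = [], [], []
    for spec in specs:
        lc = np.log(np.asarray(spec.center))
        mu = (lc - lc.mean()) @ basis.basis.T
        sd = np.sqrt(spec.total_variance / (D - 1))
        z = rng.normal(loc=mu, scale=sd, size=(spec.n, D - 1))
        comp = ilr_inv(z, basis, kappa=100.0)
        if spec.trace_zero_prob:
            for p, q in spec.trace_zero_prob.items():
                j = parts.index(p)
                zero = rng.random(spec.n) < q
                comp[zero, j] = 0.0
            comp = 100.0 * comp / comp.sum(axis=1, keepdims=True)
        tag = spec.name.replace(" ", "_")
        for i in range(spec.n):
            ids.append(f"{tag}_{i + 1:03d}")
            labels.append(spec.name)
        rows.append(comp)
    values = np.vstack(rows)
    meta = pd.DataFrame({"true_cluster": labels})
    if prep is not None:
        meta["prep"] = prep
    table = CompositionTable(ids, list(parts), values, meta)
    truth = pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="true_cluster")
    return table, truth


def _pseudo_voigt(x: np.ndarray, center: float, fwhm: float, amplitude: float,
                  eta: float = 0.5) -> np.ndarray:
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    gamma = fwhm / 2
    lorentz = gamma**2 / ((x - center) ** 2 + gamma**2)
    return amplitude * (eta * lorentz + (1 - eta) * gauss)


def generate_raman_spectrum(
    bands: Sequence[tuple[float, float, float]] = CALCITE_BANDS,
    baseline: Sequence[float] = (0.05, 1e-4),
    noise_sd: float = 0.01,
    grid: tuple[float, float, float] = (100.0, 1400.0, 1.0),
    seed: int = 0,
    eta: float = 0.5,
) -> Spectrum:
    """Synthesize a Raman spectrum: pseudo-Voigt bands + baseline + noise.

    ``bands`` is a list of (center cm^-1, FWHM cm^-1, amplitude);
    ``baseline`` polynomial coefficients in ascending order evaluated on
    the shift grid; ``noise_sd`` the Gaussian noise level in the same
    arbitrary intensity units as the amplitudes. Deterministic given the
    seed.
    """
    start, stop, step = grid
    if step <= 0 or stop <= start:
        raise CompositionError("invalid grid")
    x = np.arange(start, stop + step / 2, step)
    for c, fwhm, amp in bands:
        if not (start <= c <= stop):
            raise CompositionError(f"band at {c} cm^-1 outside the grid")
    y = npoly.polyval(x, np.asarray(baseline, dtype=float))
    for c, fwhm, amp in bands:
        y = y + _pseudo_voigt(x, c, fwhm, amp, eta)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return Spectrum(shift=x, intensity=y, meta=f"synthetic (seed={seed})")
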