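"""Ground-truthed synthetic data for every stage of the toolkit.

No public dataset of calibrated FRET z-stacks exists, so the generators
here emulate the measurement physics end to end:

* two diffraction-limited clusters per cell (sister-kinetochore geometry:
  ~800 nm apart in metaphase, ~4.5 um in anaphase), rendered as 3-D
  Gaussian spots on the 160 nm / 200 nm camera grid;
* per-cell donor/acceptor brightness multipliers (truncated normal with
  the measured channel variabilities, sigma_donor = 0.114 and
  sigma_acceptor = 0.166 — the acceptor is noisier because chromophore
  maturation varies from cell to cell);
* binomial acceptor maturation (dark acceptors), spectral mixing with
  bleed-through ``alpha`` and cross-excitation ``beta``, donor quenching
  by the true per-pair efficiency;
* per-voxel Poisson shot noise, a constant camera offset and Gaussian
  read noise;
* TCSPC decays sampled photon-by-photon from an IRF-convolved exponential
  mixture.

Everything is a pure function of (parameters, seed), and each generator
returns the ground truth alongside the data so closure tests can compare
recovered against generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .flim import DecayHistogram, InstrumentResponse
from .types import (
    CHANNELS,
    ChannelStack,
    DEFAULT_PIXEL_SIZE_NM,
    DEFAULT_Z_STEP_NM,
    InvalidInputError,
)

__all__ = [
    "CellTruth",
    "ClusterIntensities",
    "RenderedCell",
    "SyntheticDataset",
    "channel_intensities",
    "render_cell",
    "generate_calibration_dataset",
    "implied_calibration_points",
    "generate_decay",
]

#: Cluster separations by cell-cycle phase (nm).
PHASE_SEPARATION_NM = {"metaphase": 800.0, "anaphase": 4500.0}


@dataclass
class CellTruth:
    """Generating parameters of one synthetic two-cluster cell.

    ``n_pairs`` is the number of donor/acceptor-labelled protein pairs per
    cluster (16 kinetochores x 8 complexes by default).  ``brightness_*``
    are integrated camera counts per bright fluorophore.  ``e_true`` is the
    per-pair FRET efficiency; ``maturation_fraction`` the probability that
    an acceptor is bright (donor maturation is taken as complete, which is
    what the flat donor-channel variability implies).  ``gamma`` is the
    sensitized-detection factor converting quenched donor counts into
    FRET-channel acceptor counts.
    """

    cell_id: str = "cell"
    phase: str = "metaphase"
    separation_nm: float | None = None
    n_pairs: int = 128
    brightness_donor: float = 40.0
    brightness_acceptor: float = 20.0
    e_true: float = 0.0
    maturation_fraction: float = 1.0
    sigma_donor: float = 0.114
    sigma_acceptor: float = 0.166
    alpha: float = 0.058
    beta: float = 0.061
    gamma: float = 1.0
    psf_sigma_xy_nm: float = 110.0
    psf_sigma_z_nm: float = 300.0
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    z_step_nm: float = DEFAULT_Z_STEP_NM
    has_donor: bool = True
    has_acceptor: bool = True

    def __post_init__(self) -> None:
        if self.phase not in PHASE_SEPARATION_NM:
            raise InvalidInputError(f"unknown phase {self.phase!r}")
        if self.separation_nm is None:
            self.separation_nm = PHASE_SEPARATION_NM[self.phase]
        for frac in (self.e_true, self.maturation_fraction, self.alpha, self.beta):
            if not (0 <= frac <= 1):
                raise InvalidInputError("fractions must lie in [0, 1]")
        if min(self.brightness_donor, self.brightness_acceptor) < 0:
            raise InvalidInputError("brightness must be >= 0")

    def to_dict(self) -> dict:
        return {"type": "CellTruth", **asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CellTruth":
        return cls(**{k: v for k, v in d.items() if k != "type"})


@dataclass
class ClusterIntensities:
    """Noise-free expected integrated counts of one cluster, plus internals."""

    i_donor: float
    i_acceptor: float
    i_fret: float
    se_true: float
    n_acceptor_fluor: float
    f_paired: float
    g_donor: float
    g_acceptor: float


def channel_intensities(
    truth: CellTruth,
    rng: np.random.Generator | None = None,
    g: tuple[float, float] | None = None,
) -> ClusterIntensities:
    """Expected donor/acceptor/FRET integrated counts for one cluster.

    With ``rng`` the per-cell brightness multipliers and the binomial
    acceptor-maturation draw are realized; without it the deterministic
    expectation is returned (multipliers 1, bright-acceptor fraction equal
    to ``maturation_fraction``).  ``g`` pins the (donor, acceptor)
    brightness multipliers, so the two clusters of one cell can share them.

    The closure model: every donor is bright; a donor paired with a bright
    acceptor (fraction ``f``) is quenched by ``e_true``; sensitized
    emission re-emits the quenched counts scaled by ``gamma``; the FRET
    channel adds bleed-through and cross-excitation on top.
    """
    n = truth.n_pairs
    if rng is None:
        g_d, g_a = g if g is not None else (1.0, 1.0)
        n_a_fluor = truth.maturation_fraction * n if truth.has_acceptor else 0.0
    else:
        if g is not None:
            g_d, g_a = g
        else:
            g_d = max(0.0, rng.normal(1.0, truth.sigma_donor))
            g_a = max(0.0, rng.normal(1.0, truth.sigma_acceptor))
        n_a_fluor = (
            float(rng.binomial(n, truth.maturation_fraction)) if truth.has_acceptor else 0.0
        )
    f = n_a_fluor / n if n else 0.0
    if truth.has_donor:
        i_donor = g_d * truth.brightness_donor * n * (1.0 - truth.e_true * f)
        se_true = g_d * truth.brightness_donor * n * truth.e_true * f * truth.gamma
    else:
        i_donor = 0.0
        se_true = 0.0
    i_acceptor = g_a * truth.brightness_acceptor * n_a_fluor
    i_fret = se_true + truth.alpha * i_donor + truth.beta * i_acceptor
    return ClusterIntensities(
        i_donor=i_donor,
        i_acceptor=i_acceptor,
        i_fret=i_fret,
        se_true=se_true,
        n_acceptor_fluor=n_a_fluor,
        f_paired=f,
        g_donor=g_d,
        g_acceptor=g_a,
    )


@dataclass
class RenderedCell:
    """One synthetic cell: stacks per channel, cluster truths and positions."""

    truth: CellTruth
    stacks: dict[str, ChannelStack] | None
    clusters: list[ClusterIntensities]
    positions: list[tuple[float, float, float]]  # (z, y, x) in voxel units


def _render_spot(
    voxels: np.ndarray,
    position: tuple[float, float, float],
    mass: float,
    sigma_xy_px: float,
    sigma_z_px: float,
) -> None:
    """Add a 3-D Gaussian spot of the given integrated mass in place."""
    nz, ny, nx = voxels.shape
    z0, y0, x0 = position
    zz = np.arange(nz, dtype=float)[:, None, None]
    yy = np.arange(ny, dtype=float)[None, :, None]
    xx = np.arange(nx, dtype=float)[None, None, :]
    kernel = np.exp(
        -0.5 * (
            ((zz - z0) / sigma_z_px) ** 2
            + ((yy - y0) / sigma_xy_px) ** 2
            + ((xx - x0) / sigma_xy_px) ** 2
        )
    )
    norm = (2.0 * np.pi) ** 1.5 * sigma_xy_px**2 * sigma_z_px
    voxels += mass * kernel / norm


def render_cell(
    truth: CellTruth,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    nz: int = 11,
    margin_px: int = 16,
) -> RenderedCell:
    """Render a two-cluster cell into three channel stacks.

    Both clusters share the cell's brightness multipliers but draw
    independent acceptor-maturation counts.  ``noise=False`` produces the
    deterministic expected image (no Poisson/read noise, no camera offset),
    whose per-channel voxel sums match the expected integrated counts up to
    the grid-truncation error of the finite stack.
    """
    if rng is None:
        rng = np.random.default_rng()
        if noise:
            raise InvalidInputError("noisy rendering requires an explicit rng")
    sep_px = truth.separation_nm / truth.pixel_size_nm
    nx = int(np.ceil(sep_px)) + 2 * margin_px
    ny = 2 * margin_px
    sigma_xy_px = truth.psf_sigma_xy_nm / truth.pixel_size_nm
    sigma_z_px = truth.psf_sigma_z_nm / truth.z_step_nm
    zc = (nz - 1) / 2.0
    yc = ny / 2.0
    x_left = (nx - sep_px) / 2.0
    positions = [(zc, yc, x_left), (zc, yc, x_left + sep_px)]

    if noise:
        # Brightness multipliers are a per-cell property shared by both
        # clusters; acceptor maturation is drawn per cluster.
        g_cell = (
            max(0.0, rng.normal(1.0, truth.sigma_donor)),
            max(0.0, rng.normal(1.0, truth.sigma_acceptor)),
        )
        clusters = [channel_intensities(truth, rng, g=g_cell) for _ in positions]
    else:
        clusters = [channel_intensities(truth, None) for _ in positions]
    stacks: dict[str, ChannelStack] = {}
    for channel in CHANNELS:
        voxels = np.zeros((nz, ny, nx))
        for cluster, pos in zip(clusters, positions):
            mass = {
                "donor": cluster.i_donor,
                "acceptor": cluster.i_acceptor,
                "fret": cluster.i_fret,
            }[channel]
            if mass > 0:
                _render_spot(voxels, pos, mass, sigma_xy_px, sigma_z_px)
        if noise:
            voxels = rng.poisson(voxels).astype(float)
            voxels += truth.camera_offset
            voxels += rng.normal(0.0, truth.read_noise_sd, voxels.shape)
            voxels = np.clip(voxels, 0.0, None)
        stacks[channel] = ChannelStack(
            voxels,
            pixel_size_nm=truth.pixel_size_nm,
            z_step_nm=truth.z_step_nm,
            channel=channel,
        )
    return RenderedCell(truth=truth, stacks=stacks, clusters=clusters, positions=positions)


@dataclass
class SyntheticDataset:
    """A collection of rendered cells plus a CSV-serializable truth table."""

    cells: list[RenderedCell]
    table: pd.DataFrame = field(repr=False, default=None)


def _truth_rows(strain: str, cell: RenderedCell) -> list[dict]:
    rows = []
    for idx, (cluster, pos) in enumerate(zip(cell.clusters, cell.positions)):
        rows.append(
            {
                "cell_id": cell.truth.cell_id,
                "strain": strain,
                "phase": cell.truth.phase,
                "cluster": idx,
                "e_true": cell.truth.e_true,
                "maturation_fraction": cell.truth.maturation_fraction,
                "z": pos[0],
                "y": pos[1],
                "x": pos[2],
                "i_donor_true": cluster.i_donor,
                "i_acceptor_true": cluster.i_acceptor,
                "i_fret_true": cluster.i_fret,
                "se_true": cluster.se_true,
            }
        )
    return rows


def generate_calibration_dataset(
    fret_strains: tuple[tuple[float, int], ...] = ((0.02, 170), (0.10, 170), (0.25, 170)),
    n_donor_only: int = 170,
    n_acceptor_only: int = 100,
    phase: str = "metaphase",
    seed: int | None = None,
    render: bool = True,
    noise: bool = True,
    **truth_overrides,
) -> SyntheticDataset:
    """Synthetic calibration experiment: FRET strains plus single-label controls.

    ``fret_strains`` lists (true per-pair efficiency, number of cells).
    Donor-only cells fix the unquenched donor brightness for donor-quenching
    efficiency estimates and the bleed-through coefficient; acceptor-only
    cells fix cross-excitation.  The truth table carries the generating
    intensities for every cluster.
    """
    rng = np.random.default_rng(seed)
    base = CellTruth(phase=phase, **truth_overrides)
    cells: list[RenderedCell] = []
    rows: list[dict] = []

    def emit(strain: str, truth: CellTruth, count: int) -> None:
        for i in range(count):
            t = replace(truth, cell_id=f"{strain}_{i:04d}")
            if render:
                cell = render_cell(t, rng, noise=noise)
            else:
                g_cell = (
                    max(0.0, rng.normal(1.0, t.sigma_donor)),
                    max(0.0, rng.normal(1.0, t.sigma_acceptor)),
                )
                cell = RenderedCell(
                    truth=t,
                    stacks=None,
                    clusters=[
                        channel_intensities(t, rng, g=g_cell),
                        channel_intensities(t, rng, g=g_cell),
                    ],
                    positions=[(0, 0, 0), (0, 0, 0)],
                )
            cells.append(cell)
            rows.extend(_truth_rows(strain, cell))

    emit("donor_only", replace(base, e_true=0.0, has_acceptor=False), n_donor_only)
    emit("acceptor_only", replace(base, e_true=0.0, has_donor=False), n_acceptor_only)
    for e_true, count in fret_strains:
        emit(f"fret_e{e_true:g}", replace(base, e_true=float(e_true)), count)
    return SyntheticDataset(cells=cells, table=pd.DataFrame(rows))


def implied_calibration_points(
    fret_strains,
    truth_template: CellTruth | None = None,
) -> pd.DataFrame:
    """Noise-free (proximity ratio, apparent efficiency) point per strain.

    Evaluates the generator's expectation algebra: the apparent
    donor-quenching efficiency is ``e_true * maturation_fraction`` and the
    proximity ratio follows from the expected channel intensities.  The
    slope of the line through these points is the generator-implied
    calibration slope that a full pipeline run should recover.
    """
    base = truth_template or CellTruth()
    rows = []
    for e_true, *_ in ([s if isinstance(s, (tuple, list)) else (s,) for s in fret_strains]):
        t = replace(base, e_true=float(e_true))
        c = channel_intensities(t, rng=None)
        denom = t.alpha * c.i_donor + t.beta * c.i_acceptor
        rows.append(
            {
                "e_true": t.e_true,
                "e_apparent": t.e_true * t.maturation_fraction,
                "proximity_ratio": c.se_true / denom,
            }
        )
    return pd.DataFrame(rows)


def generate_decay(
    components: list[tuple[float, float]],
    irf_width_ns: float = 0.1,
    irf_center_ns: float = 0.5,
    n_photons: int = 100_000,
    n_bins: int = 256,
    t_max_ns: float = 12.5,
    seed: int | None = None,
) -> tuple[DecayHistogram, InstrumentResponse]:
    """Sample a TCSPC histogram from an IRF-convolved exponential mixture.

    ``components`` is [(amplitude, lifetime_ns), ...] in decay-amplitude
    convention; the photon count of component i is proportional to
    ``A_i * tau_i`` (its area).  Arrival time = Gaussian IRF draw plus an
    exponential lifetime draw; photons outside [0, t_max_ns) are discarded,
    which truncates but does not distort the within-window decay shape.
    A ``irf_width_ns`` of 0 gives pure exponential sampling from
    ``irf_center_ns``.
    """
    if not components:
        raise InvalidInputError("at least one decay component is required")
    rng = np.random.default_rng(seed)
    amps = np.array([a for a, _ in components], dtype=float)
    taus = np.array([t for _, t in components], dtype=float)
    if np.any(amps < 0) or np.any(taus <= 0):
        raise InvalidInputError("amplitudes must be >= 0 and lifetimes > 0")
    weights = amps * taus
    weights = weights / weights.sum()
    which = rng.choice(len(components), size=n_photons, p=weights)
    t_exp = rng.exponential(taus[which])
    t_irf = (
        np.full(n_photons, irf_center_ns)
        if irf_width_ns == 0
        else rng.normal(irf_center_ns, irf_width_ns, n_photons)
    )
    t = t_exp + t_irf
    t = t[(t >= 0) & (t < t_max_ns)]
    edges = np.linspace(0.0, t_max_ns, n_bins + 1)
    counts, _ = np.histogram(t, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if irf_width_ns == 0:
        irf_amp = np.zeros(n_bins)
        irf_amp[int(np.clip(irf_center_ns / (t_max_ns / n_bins), 0, n_bins - 1))] = 1.0
    else:
        irf_amp = np.exp(-0.5 * ((centers - irf_center_ns) / irf_width_ns) ** 2)
    return DecayHistogram(edges, counts), InstrumentResponse(edges, irf_amp)
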