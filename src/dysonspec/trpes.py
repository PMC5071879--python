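"""Time-resolved photoelectron spectra from surface-hopping trajectory ensembles.

A trajectory record carries, per time step, the spin-mixed state weights
w_j(t) (squared amplitudes of the states contributing to the active state),
state potentials V_j(t), and per ionization channel (j, alpha) the ion
potential V_alpha(t) and the Dyson norm.  At each step every open channel
(binding energy dE = V_alpha - V_j between 0 and the probe energy) emits a
stick at kinetic energy E_kin = probe - dE with intensity w_j * A, where A
is the amplitude W = dE * norm (default, consistent with the static
spectra) or the bare Dyson norm.

Sticks are pooled over trajectories (per-bin weight: tautomer fraction
divided by the number of trajectories of that tautomer contributing to the
bin), Gaussian-broadened along the energy axis, convolved in time with the
instrument cross-correlation, integrated over a kinetic-energy window, and
decomposed by tautomer, attributed neutral state, or mechanistic pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import FWHM_TO_SIGMA, energy_grid

#: gas-phase tautomer ratio used for mixing keto and enol ensembles
DEFAULT_TAUTOMER_WEIGHTS = {"keto": 35.0, "enol": 65.0}

_SLICE_TOL = 1e-8


class StrideError(ValueError):
    """Trajectories with inconsistent time strides cannot be pooled."""


@dataclass
class ChannelSeries:
    """Time series of one ionization channel (source state j -> ion alpha)."""

    source: str
    ion: str
    v_ion: np.ndarray  # eV
    norm: np.ndarray

    def __post_init__(self) -> None:
        self.v_ion = np.asarray(self.v_ion, dtype=float)
        self.norm = np.asarray(self.norm, dtype=float)
        if self.v_ion.shape != self.norm.shape:
            raise ValueError("channel series lengths differ")
        if np.any(self.norm < 0):
            raise ValueError("Dyson norms must be non-negative")


@dataclass
class TrajectoryRecord:
    """Per-trajectory time series with pathway and tautomer labels."""

    traj_id: str
    tautomer: str
    pathway: str
    times: np.ndarray  # fs, uniform stride
    weights: dict[str, np.ndarray]  # state label -> w_j(t), sum_j = 1
    energies: dict[str, np.ndarray]  # state label -> V_j(t), eV
    channels: list[ChannelSeries]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) < 1:
            raise ValueError("empty trajectory")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise StrideError("non-uniform time stride")
        wsum = np.zeros_like(self.times)
        for label, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            self.weights[label] = w
            if w.shape != self.times.shape:
                raise ValueError(f"weight series for {label} has wrong length")
            if np.any(w < -1e-12):
                raise ValueError("state weights must be non-negative")
            wsum += w
        if not np.allclose(wsum, 1.0, atol=1e-6):
            raise ValueError("state weights must sum to 1 at every step")
        for label, v in self.energies.items():
            self.energies[label] = np.asarray(v, dtype=float)
            if self.energies[label].shape != self.times.shape:
                raise ValueError(f"energy series for {label} has wrong length")
        for ch in self.channels:
            if ch.v_ion.shape != self.times.shape:
                raise ValueError("channel series length differs from times")
            if ch.source not in self.weights or ch.source not in self.energies:
                raise ValueError(f"channel source {ch.source!r} unknown to record")

    @property
    def stride(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class TRPESGrid:
    """Intensity on a (time, kinetic energy) grid with decomposition slices.

    ``slices`` maps (tautomer, state, pathway) keys to intensity matrices;
    the total is their exact sum.
    """

    times: np.ndarray  # fs
    energies: np.ndarray  # eV, kinetic
    intensity: np.ndarray  # (n_times, n_energies)
    slices: dict[tuple[str, str, str], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.intensity.shape != (len(self.times), len(self.energies)):
            raise ValueError("intensity shape does not match axes")
        if self.slices:
            total = sum(self.slices.values())
            if not np.allclose(total, self.intensity, atol=_SLICE_TOL):
                raise ValueError("decomposition slices do not sum to the total")


def step_channel_intensities(
    record: TrajectoryRecord,
    t_index: int,
    probe_energy: float,
    mode: str = "W",
) -> list[tuple[float, float, str]]:
    """Open-channel sticks (E_kin, intensity, source state) at one time step.

    ``mode="W"`` weights each channel by w_j * dE * norm (amplitude form used
    for the static spectra); ``mode="norm"`` uses the bare Dyson norm,
    w_j * norm.  Channels with dE < 0 or dE > probe are omitted.
    """
    if probe_energy <= 0:
        raise ValueError("probe energy must be positive")
    if mode not in ("W", "norm"):
        raise ValueError("mode must be 'W' or 'norm'")
    out = []
    for ch in record.channels:
        dE = float(ch.v_ion[t_index] - record.energies[ch.source][t_index])
        if dE < 0 or dE > probe_energy:
            continue
        w = float(record.weights[ch.source][t_index])
        amp = ch.norm[t_index] * (dE if mode == "W" else 1.0)
        intensity = w * amp
        if intensity != 0.0:
            out.append((probe_energy - dE, intensity, ch.source))
    return out


def assemble_trpes(
    records: list[TrajectoryRecord],
    probe_energy: float,
    kinetic_grid=(0.0, 5.4, 0.02),
    energy_fwhm: float = 0.2,
    mode: str = "W",
    tautomer_weights: dict[str, float] | None = None,
    normalization: str = "contributing",
) -> TRPESGrid:
    """Pool an ensemble of trajectories into a broadened (t, E_kin) grid.

    All records must share one time stride and a common time origin grid
    (resampling is refused).  Per time bin, each trajectory of tautomer T
    contributes with weight ``frac(T) / n(T, bin)`` where ``n(T, bin)`` is
    the number of tautomer-T trajectories covering the bin
    (``normalization="contributing"``) or the total count
    (``normalization="total"``).  Tautomer fractions default to
    keto:enol = 35:65, restricted and renormalised over the tautomers
    actually present.  Decomposition slices keyed by (tautomer, attributed
    state, pathway) are attached; the total equals their sum.
    """
    if not records:
        raise ValueError("empty ensemble")
    if normalization not in ("contributing", "total"):
        raise ValueError("normalization must be 'contributing' or 'total'")
    strides = {round(r.stride, 9) for r in records if len(r.times) > 1}
    if len(strides) > 1:
        raise StrideError(f"mixed strides {sorted(strides)}; resampling refused")
    dt = strides.pop() if strides else 0.0

    t0 = min(float(r.times[0]) for r in records)
    t_end = max(float(r.times[-1]) for r in records)
    if dt > 0:
        for r in records:
            off = (r.times[0] - t0) / dt
            if abs(off - round(off)) > 1e-6:
                raise StrideError("trajectory time origins are not grid-aligned")
        n_t = int(round((t_end - t0) / dt)) + 1
        times = t0 + dt * np.arange(n_t)
    else:
        times = np.array([t0])
        n_t = 1

    egrid = energy_grid(kinetic_grid)
    sigma = energy_fwhm * FWHM_TO_SIGMA
    gauss_norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))

    present = sorted({r.tautomer for r in records})
    if tautomer_weights is None:
        raw = DEFAULT_TAUTOMER_WEIGHTS
        if not all(t in raw for t in present):
            raw = {t: 1.0 for t in present}
    else:
        raw = tautomer_weights
        missing = [t for t in present if t not in raw]
        if missing:
            raise ValueError(f"no tautomer weight for {missing}")
    wsum = sum(raw[t] for t in present)
    taut_frac = {t: raw[t] / wsum for t in present}

    # per-tautomer trajectory coverage per bin
    coverage: dict[str, np.ndarray] = {t: np.zeros(n_t) for t in present}
    bin_index: list[np.ndarray] = []
    for r in records:
        start = int(round((r.times[0] - t0) / dt)) if dt > 0 else 0
        idx = start + np.arange(len(r.times))
        bin_index.append(idx)
        coverage[r.tautomer][idx] += 1.0

    slices: dict[tuple[str, str, str], np.ndarray] = {}
    for r, idx in zip(records, bin_index):
        if normalization == "contributing":
            denom = coverage[r.tautomer][idx]
        else:
            denom = np.full(len(idx), sum(1 for x in records if x.tautomer == r.tautomer))
        traj_w = taut_frac[r.tautomer] / denom  # per covered bin
        for ch in r.channels:
            dE = ch.v_ion - r.energies[ch.source]
            open_mask = (dE >= 0) & (dE <= probe_energy)
            if not np.any(open_mask):
                continue
            amp = ch.norm * (dE if mode == "W" else 1.0)
            intensity = r.weights[ch.source] * amp * traj_w
            intensity = np.where(open_mask, intensity, 0.0)
            ekin = probe_energy - dE
            rows = gauss_norm * np.exp(
                -0.5 * ((egrid[None, :] - ekin[:, None]) / sigma) ** 2
            )
            contrib = intensity[:, None] * rows
            key = (r.tautomer, ch.source, r.pathway)
            mat = slices.setdefault(key, np.zeros((n_t, len(egrid))))
            np.add.at(mat, idx, contrib)

    total = sum(slices.values()) if slices else np.zeros((n_t, len(egrid)))
    return TRPESGrid(
        times=times,
        energies=egrid,
        intensity=total,
        slices=slices,
        metadata={
            "probe_energy": probe_energy,
            "energy_fwhm": energy_fwhm,
            "time_fwhm": None,
            "mode": mode,
            "tautomer_fractions": taut_frac,
            "normalization": normalization,
            "n_trajectories": len(records),
        },
    )


def convolve_time(grid: TRPESGrid, fwhm: float = 160.0) -> TRPESGrid:
    """Convolve every energy row with a unit-area Gaussian along time.

    Boundary policy: the signal is taken as zero before the first frame
    (there is no pre-pump signal) and continued by its edge value beyond the
    last frame.  The time axis must be uniform.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    t = grid.times
    if len(t) < 2:
        raise ValueError("need at least two time frames to convolve")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError("non-uniform time axis")
    step = float(dt[0])
    sigma = fwhm * FWHM_TO_SIGMA
    half = max(1, int(math.ceil(5.0 * sigma / step)))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) * step / sigma) ** 2)
    kernel /= kernel.sum()

    def conv(mat: np.ndarray) -> np.ndarray:
        pad_lo = np.zeros((half, mat.shape[1]))
        pad_hi = np.tile(mat[-1], (half, 1))
        padded = np.vstack([pad_lo, mat, pad_hi])
        out = np.empty_like(mat)
        for j in range(mat.shape[1]):
            out[:, j] = np.convolve(padded[:, j], kernel, mode="valid")
        return out

    new_slices = {k: conv(v) for k, v in grid.slices.items()}
    total = sum(new_slices.values()) if new_slices else conv(grid.intensity)
    return TRPESGrid(
        times=t.copy(),
        energies=grid.energies.copy(),
        intensity=total,
        slices=new_slices,
        metadata={**grid.metadata, "time_fwhm": fwhm},
    )


def _window_weights(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Node weights so that w @ f equals the integral of the piecewise-linear
    interpolant of f over [lo, hi]."""
    w = np.zeros_like(x)
    for i in range(len(x) - 1):
        a, b = x[i], x[i + 1]
        left, right = max(a, lo), min(b, hi)
        if right <= left:
            continue
        h = b - a
        # f(s) = f_i (b-s)/h + f_{i+1} (s-a)/h ; integrate s over [left, right]
        li = ((b - left) + (b - right)) / (2 * h) * (right - left)
        ri = ((left - a) + (right - a)) / (2 * h) * (right - left)
        w[i] += li
        w[i + 1] += ri
    return w


def integrate_energy(
    grid: TRPESGrid, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, dict[tuple[str, str, str], np.ndarray]]:
    """Energy-integrated yield trace over a kinetic-energy window.

    Trapezoidal integration with interpolated window edges.  Returns
    ``(times, total trace, per-slice traces)``; the per-slice traces sum to
    the total.  Windows partly outside the axis are clipped.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty integration window")
    e = grid.energies
    lo_c, hi_c = max(lo, e[0]), min(hi, e[-1])
    if hi_c <= lo_c:
        raise ValueError("window lies entirely outside the energy axis")
    w = _window_weights(e, lo_c, hi_c)
    slice_traces = {k: v @ w for k, v in grid.slices.items()}
    total = (
        sum(slice_traces.values()) if slice_traces else grid.intensity @ w
    )
    return grid.times.copy(), total, slice_traces


def decompose(grid: TRPESGrid, by: str) -> dict[str, np.ndarray]:
    """Sum decomposition slices by ``"tautomer"``, ``"state"`` or ``"pathway"``.

    Fractional state attribution was recorded at assembly (each channel's
    signal carries its source-state weight); pathway and tautomer labels are
    exclusive per trajectory.  The returned slices sum to the total grid.
    """
    axes = {"tautomer": 0, "state": 1, "pathway": 2}
    if by not in axes:
        raise ValueError("by must be one of 'tautomer', 'state', 'pathway'")
    if not grid.slices:
        raise ValueError(
            "no decomposition attached; re-assemble the grid with assemble_trpes"
        )
    ax = axes[by]
    out: dict[str, np.ndarray] = {}
    for key, mat in grid.slices.items():
        label = key[ax]
        if label in out:
            out[label] = out[label] + mat
        else:
            out[label] = mat.copy()
    return out


def save_trajectory(directory: str, record: TrajectoryRecord) -> None:
    """Write one trajectory as delimiter-separated text plus JSON metadata.

    Layout: ``<dir>/meta.json`` (id, tautomer, pathway, state/channel
    listing) and ``<dir>/series.tsv`` with one row per time step.
    """
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    states = sorted(record.weights)
    channels = [(ch.source, ch.ion) for ch in record.channels]
    meta = {
        "traj_id": record.traj_id,
        "tautomer": record.tautomer,
        "pathway": record.pathway,
        "states": states,
        "channels": channels,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)

    cols = [record.times]
    header = ["time_fs"]
    for s in states:
        cols += [record.weights[s], record.energies[s]]
        header += [f"w[{s}]", f"V[{s}]"]
    for ch in record.channels:
        cols += [ch.v_ion, ch.norm]
        header += [f"Vion[{ch.source}->{ch.ion}]", f"norm[{ch.source}->{ch.ion}]"]
    np.savetxt(
        os.path.join(directory, "series.tsv"),
        np.column_stack(cols),
        delimiter="\t",
        header="\t".join(header),
    )


def load_trajectory(directory: str) -> TrajectoryRecord:
    """Read a trajectory written by :func:`save_trajectory`."""
    import json
    import os

    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    data = np.loadtxt(os.path.join(directory, "series.tsv"), delimiter="\t", ndmin=2)
    states = meta["states"]
    times = data[:, 0]
    weights, energies = {}, {}
    col = 1
    for s in states:
        weights[s] = data[:, col]
        energies[s] = data[:, col + 1]
        col += 2
    channels = []
    for source, ion in meta["channels"]:
        channels.append(
            ChannelSeries(source=source, ion=ion, v_ion=data[:, col], norm=data[:, col + 1])
        )
        col += 2
    return TrajectoryRecord(
        traj_id=meta["traj_id"],
        tautomer=meta["tautomer"],
        pathway=meta["pathway"],
        times=times,
        weights=weights,
        energies=energies,
        channels=channels,
    )


def save_ensemble(directory: str, records: list[TrajectoryRecord]) -> None:
    """Write an ensemble, one subdirectory per trajectory."""
    import os

    for record in records:
        save_trajectory(os.path.join(directory, record.traj_id), record)


def load_ensemble(directory: str) -> list[TrajectoryRecord]:
    """Read every trajectory subdirectory of an ensemble directory."""
    import os

    records = []
    for name in sorted(os.listdir(directory)):
        sub = os.path.join(directory, name)
        if os.path.isdir(sub) and os.path.exists(os.path.join(sub, "meta.json")):
            records.append(load_trajectory(sub))
    if not records:
        raise ValueError(f"no trajectories found under {directory}")
    return records


def write_trpes(path: str, grid: TRPESGrid, delimiter: str = "\t") -> None:
    """Gridded text matrix (first row energies, first column times) with a
    JSON metadata sidecar."""
    import json

    with open(path, "w") as fh:
        fh.write("# time_fs\\ekin_eV" + delimiter)
        fh.write(delimiter.join(f"{e:.6g}" for e in grid.energies) + "\n")
        for t, row in zip(grid.times, grid.intensity):
            fh.write(
                f"{t:.6g}" + delimiter + delimiter.join(f"{v:.8e}" for v in row) + "\n"
            )
    meta = dict(grid.metadata)
    meta["slices"] = sorted("|".join(k) for k in grid.slices)
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
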