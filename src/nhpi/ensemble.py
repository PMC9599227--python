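"""Ensemble views of NH-pi geometry: ring superposition, density maps,
cutoff occupancy over trajectories, and melting-curve analysis.

Trajectories enter as multi-model structures; per-frame six-parameter
series are binned into 2-D occurrence-fraction maps with a per-bin mean of
a third (colour) parameter, and the fraction of frames satisfying the
NH-pi cutoffs is the bond's occupancy.  Thermal unfolding curves are
reduced to a melting temperature by baseline-normalising the ellipticity
to a folded fraction F(T) and interpolating the F = 0.5 crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import (
    GeometryConfig,
    GeometryError,
    build_amide_donor,
    build_ring_frame,
    compute_pair_geometry,
)
from .screening import ScreenConfig
from .structure import Structure

__all__ = [
    "DensityMap",
    "MeltCurve",
    "NoTransitionError",
    "reference_hexagon",
    "superpose_onto_reference_ring",
    "geometry_series",
    "compute_density_map",
    "cutoff_occupancy",
    "melting_temperature",
]

RING_RADIUS = 1.39  # A, aromatic C-C bond length equals the circumradius

DEFAULT_BIN_WIDTHS = {"distance": 0.1, "angle": 5.0}


class NoTransitionError(ValueError):
    """Raised when a melting curve shows no two-state transition."""


def reference_hexagon(radius: float = RING_RADIUS) -> np.ndarray:
    """Ideal planar hexagon in z = 0, counter-clockwise, vertex 0 on +x."""
    ang = np.radians(60.0 * np.arange(6))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def superpose_onto_reference_ring(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    reference: Optional[np.ndarray] = None,
) -> list[dict]:
    """Least-squares rigid superposition of each ring onto a reference.

    Parameters
    ----------
    pairs : sequence of (donor_coords (m, 3), ring_coords (6, 3))
        Ring carbons in canonical traversal order.
    reference : (6, 3) array, optional
        Target ring; defaults to the ideal hexagon.

    Returns one dict per pair with the transformed donor coordinates
    (``donor``), transformed ring (``ring``), the superposition ``rmsd``
    and the rigid transform (``rotation``, ``translation``) that maps the
    mobile frame into the reference frame.
    """
    ref = reference_hexagon() if reference is None else np.asarray(reference)
    ref_c = ref.mean(axis=0)
    out = []
    for donor_xyz, ring_xyz in pairs:
        ring_xyz = np.asarray(ring_xyz, dtype=float)
        donor_xyz = np.asarray(donor_xyz, dtype=float)
        if ring_xyz.shape != ref.shape:
            raise ValueError("ring must supply all 6 ring carbons")
        cen = ring_xyz.mean(axis=0)
        if np.linalg.matrix_rank(ring_xyz - cen, tol=1e-8) < 2:
            raise GeometryError("degenerate (collinear) ring input")
        rot, rssd = Rotation.align_vectors(ref - ref_c, ring_xyz - cen)
        R = rot.as_matrix()
        t = ref_c - R @ cen
        out.append(
            {
                "donor": donor_xyz @ R.T + t,
                "ring": ring_xyz @ R.T + t,
                "rmsd": float(rssd / np.sqrt(len(ref))),
                "rotation": R,
                "translation": t,
            }
        )
    return out


def geometry_series(
    structure: Structure,
    donor_address: tuple[str, int],
    ring_address: tuple[str, int],
    config: Optional[GeometryConfig] = None,
) -> pd.DataFrame:
    """Six-parameter series over every model for one donor-ring pair.

    Addresses are (chain_id, seqnum) tuples; one row per model/frame.
    """
    config = config or GeometryConfig()
    rows = []
    for model in structure.models:
        d_chain = model.get_chain(donor_address[0])
        r_chain = model.get_chain(ring_address[0])
        if d_chain is None or r_chain is None:
            raise KeyError(f"chain missing in model {model.index}")
        d_res = d_chain.get(donor_address[1])
        r_res = r_chain.get(ring_address[1])
        if d_res is None or r_res is None:
            raise KeyError(f"residue missing in model {model.index}")
        donor = build_amide_donor(d_res, config)
        ring = build_ring_frame(r_res)
        geom = compute_pair_geometry(donor, ring, config)
        rows.append({"frame": model.index, **geom.as_dict()})
    return pd.DataFrame(rows)


@dataclass
class DensityMap:
    a_name: str
    b_name: str
    color_name: Optional[str]
    a_edges: np.ndarray
    b_edges: np.ndarray
    fraction: np.ndarray  # (na, nb), sums to 1 over occupied bins
    mean_color: np.ndarray  # (na, nb), NaN where empty
    modal_bin: tuple[int, int]
    modal_midpoint: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        a_mid = 0.5 * (self.a_edges[:-1] + self.a_edges[1:])
        b_mid = 0.5 * (self.b_edges[:-1] + self.b_edges[1:])
        ia, ib = np.nonzero(self.fraction)
        return pd.DataFrame(
            {
                self.a_name: a_mid[ia],
                self.b_name: b_mid[ib],
                "fraction": self.fraction[ia, ib],
                f"mean_{self.color_name}": self.mean_color[ia, ib],
            }
        )


def _auto_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def compute_density_map(
    series: pd.DataFrame,
    axes: tuple[str, str],
    color: Optional[str] = None,
    bin_widths: Optional[tuple[float, float]] = None,
) -> DensityMap:
    """2-D occurrence-fraction histogram with a per-bin colour mean.

    Default bin widths: 0.1 A for distance-like axes (name starts with
    ``d_``), 5 deg for angles.  The modal bin is the maximum-fraction bin;
    ties resolve toward the smaller first-axis (e.g. d_NM) value.
    """
    if len(series) == 0:
        raise ValueError("empty geometry series")
    a_name, b_name = axes
    a = np.asarray(series[a_name], dtype=float)
    b = np.asarray(series[b_name], dtype=float)
    if bin_widths is None:
        bin_widths = tuple(
            DEFAULT_BIN_WIDTHS["distance" if n.startswith("d_") else "angle"]
            for n in axes
        )
    a_edges = _auto_edges(a, bin_widths[0])
    b_edges = _auto_edges(b, bin_widths[1])
    counts, _, _ = np.histogram2d(a, b, bins=(a_edges, b_edges))
    fraction = counts / counts.sum()

    mean_color = np.full_like(fraction, np.nan)
    color_name = color
    if color is not None:
        c = np.asarray(series[color], dtype=float)
        sums, _, _ = np.histogram2d(a, b, bins=(a_edges, b_edges), weights=c)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_color = np.where(counts > 0, sums / counts, np.nan)

    flat = int(np.argmax(fraction))  # row-major: first max has smallest a
    modal = np.unravel_index(flat, fraction.shape)
    midpoint = (
        float(0.5 * (a_edges[modal[0]] + a_edges[modal[0] + 1])),
        float(0.5 * (b_edges[modal[1]] + b_edges[modal[1] + 1])),
    )
    return DensityMap(
        a_name=a_name,
        b_name=b_name,
        color_name=color_name,
        a_edges=a_edges,
        b_edges=b_edges,
        fraction=fraction,
        mean_color=mean_color,
        modal_bin=(int(modal[0]), int(modal[1])),
        modal_midpoint=midpoint,
    )


def cutoff_occupancy(
    series: pd.DataFrame, config: Optional[ScreenConfig] = None
) -> float:
    """Fraction of frames whose geometry satisfies all NH-pi cutoffs."""
    if len(series) == 0:
        raise ValueError("empty geometry series")
    config = config or ScreenConfig()
    ok = (
        (series["d_NM"] < config.cutoff_d_NM)
        & (series["theta"] < config.cutoff_theta)
        & (series["omega"] > config.cutoff_omega)
    )
    return float(ok.mean())


# ---------------------------------------------------------------------------
# melting curves


@dataclass
class MeltCurve:
    temperatures: np.ndarray
    ellipticities: np.ndarray
    folded_fit: tuple[float, float]  # slope, intercept
    unfolded_fit: tuple[float, float]
    fraction_folded: np.ndarray
    tm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature": self.temperatures,
                "ellipticity": self.ellipticities,
                "fraction_folded": self.fraction_folded,
            }
        )


def melting_temperature(
    temperatures: Sequence[float],
    ellipticities: Sequence[float],
    folded_window: Optional[tuple[float, float]] = None,
    unfolded_window: Optional[tuple[float, float]] = None,
) -> MeltCurve:
    """Two-state melting temperature from a thermal denaturation curve.

    Linear baselines are fitted to the folded (low-T) and unfolded
    (high-T) windows - by default the lowest and highest quarters of the
    temperature range - and the folded fraction is

        F(T) = (theta(T) - theta_U(T)) / (theta_F(T) - theta_U(T)).

    Tm is the temperature where F crosses 0.5, found by linear
    interpolation between bracketing samples.  A curve without a usable
    transition raises :class:`NoTransitionError`.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(ellipticities, dtype=float)
    if T.ndim != 1 or T.shape != y.shape or len(T) < 10:
        raise ValueError("need >= 10 (temperature, ellipticity) samples")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperatures must be strictly increasing")

    span = T[-1] - T[0]
    if folded_window is None:
        folded_window = (T[0], T[0] + 0.25 * span)
    if unfolded_window is None:
        unfolded_window = (T[-1] - 0.25 * span, T[-1])

    def _fit(window: tuple[float, float]) -> tuple[float, float]:
        m = (T >= window[0]) & (T <= window[1])
        if m.sum() < 2:
            raise ValueError(f"baseline window {window} holds < 2 points")
        slope, intercept = np.polyfit(T[m], y[m], 1)
        return float(slope), float(intercept)

    f_slope, f_int = _fit(folded_window)
    u_slope, u_int = _fit(unfolded_window)

    theta_f = f_slope * T + f_int
    theta_u = u_slope * T + u_int
    gap = theta_f - theta_u
    # residual scatter of the baseline fits sets the scale for "no signal"
    fm = (T >= folded_window[0]) & (T <= folded_window[1])
    um = (T >= unfolded_window[0]) & (T <= unfolded_window[1])
    resid = np.concatenate([y[fm] - theta_f[fm], y[um] - theta_u[um]])
    noise = float(np.sqrt(np.mean(resid**2)))
    floor = 1e-8 * (1.0 + float(np.max(np.abs(y))))
    if np.max(np.abs(gap)) <= max(4.0 * noise, floor):
        raise NoTransitionError("folded and unfolded baselines coincide")

    with np.errstate(invalid="ignore", divide="ignore"):
        F = (y - theta_u) / gap
    if np.nanmin(F) < -0.2 or np.nanmax(F) > 1.2:
        warnings.warn("folded fraction leaves [-0.2, 1.2]; check baselines")

    g = F - 0.5
    crossings = np.nonzero(g[:-1] * g[1:] <= 0)[0]
    crossings = [i for i in crossings if g[i] != g[i + 1] or g[i] == 0]
    if not crossings:
        raise NoTransitionError("folded fraction never crosses 0.5")
    if len(crossings) > 2:
        warnings.warn("multiple F = 0.5 crossings; reporting the first")
    i = crossings[0]
    if g[i] == 0:
        tm = float(T[i])
    else:
        tm = float(T[i] + (T[i + 1] - T[i]) * (0.5 - F[i]) / (F[i + 1] - F[i]))

    return MeltCurve(
        temperatures=T,
        ellipticities=y,
        folded_fit=(f_slope, f_int),
        unfolded_fit=(u_slope, u_int),
        fraction_folded=F,
        tm=tm,
    )
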