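"""Thin-plate-spline color correction.

The embedded chart yields n pairs (captured color c_i, reference color r_i).
For each output channel k a smoothing thin-plate spline

    f_k(c) = a0_k + a_k . c + sum_i w_ik * phi(||c - c_i||)

is fitted in 3-D RGB space by solving the block system

    [ K + lambda*I   P ] [ w ]   [ y ]
    [     P^T        0 ] [ a ] = [ 0 ],   K_ij = phi(||c_i - c_j||),
                                          P_i  = (1, c_i^T)

so that at lambda = 0 the map interpolates the control points exactly and the
side conditions sum(w) = 0, sum(w_i c_i) = 0 keep the far field affine.  The
classical TPS basis phi(r) = r^2 ln r (with phi(0) = 0) is the default; the
polyharmonic phi(r) = r is selectable.  Colors are raw 8-bit sRGB values
without linearization, mirroring direct use of captured channel values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ColorCorrectionMap",
    "DegenerateControlPointsError",
    "fit_tps_map",
    "apply_map",
    "correction_residual",
    "fit_diagonal_gains",
    "apply_diagonal_gains",
]

MIN_CONTROL_POINTS = 8


class DegenerateControlPointsError(ValueError):
    """Control points do not span 3-D color space (rank-deficient system)."""


def _phi(r: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "r2logr":
        safe = np.where(r > 0, r, 1.0)
        return np.where(r > 0, r * r * np.log(safe), 0.0)
    if kernel == "r":
        return r
    raise ValueError(f"unknown kernel {kernel!r}; expected 'r2logr' or 'r'")


@dataclass
class ColorCorrectionMap:
    """Fitted map from captured color space to reference color space."""

    control_points: np.ndarray   # (n, 3) captured colors
    weights: np.ndarray          # (n, 3), one column per output channel
    affine: np.ndarray           # (4, 3): row 0 = a0, rows 1..3 = a
    kernel: str = "r2logr"
    lam: float = 0.0

    def __call__(self, colors) -> np.ndarray:
        return apply_map(self, colors)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "control_points": self.control_points.tolist(),
            "weights": self.weights.tolist(),
            "affine": self.affine.tolist(),
            "kernel": self.kernel,
            "lambda": self.lam,
        }, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ColorCorrectionMap":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            raw = json.loads(Path(source).read_text())
        else:
            raw = json.loads(source)
        return cls(
            control_points=np.asarray(raw["control_points"], dtype=float),
            weights=np.asarray(raw["weights"], dtype=float),
            affine=np.asarray(raw["affine"], dtype=float),
            kernel=raw["kernel"],
            lam=float(raw["lambda"]),
        )


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of PatchMeasurement-likes or a (captured, reference) tuple."""
    if isinstance(pairs, tuple) and len(pairs) == 2:
        return (np.asarray(pairs[0], dtype=float), np.asarray(pairs[1], dtype=float))
    cap = np.asarray([p.captured_rgb for p in pairs], dtype=float)
    ref = np.asarray([p.reference_rgb for p in pairs], dtype=float)
    return cap, ref


def fit_tps_map(pairs, lam: float = 0.0, kernel: str = "r2logr") -> ColorCorrectionMap:
    """Fit the three per-channel splines from captured/reference pairs.

    ``pairs`` is either a list of objects with ``captured_rgb`` and
    ``reference_rgb`` attributes, or a tuple ``(captured, reference)`` of
    (n, 3) arrays.  Requires n >= 8 and captured colors spanning 3-D space.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    cap, ref = _pair_arrays(pairs)
    n = cap.shape[0]
    if n < MIN_CONTROL_POINTS:
        raise ValueError(f"need at least {MIN_CONTROL_POINTS} color pairs, got {n}")
    p = np.column_stack([np.ones(n), cap])
    if np.linalg.matrix_rank(p) < 4:
        raise DegenerateControlPointsError(
            "captured colors are affinely degenerate (coplanar/collinear in RGB)"
        )
    k = _phi(cdist(cap, cap), kernel)
    a = np.zeros((n + 4, n + 4))
    a[:n, :n] = k + lam * np.eye(n)
    a[:n, n:] = p
    a[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = ref
    try:
        sol = np.linalg.solve(a, rhs)
        # two steps of iterative refinement: the saddle system is poorly
        # conditioned at 8-bit color scale and this recovers ~machine accuracy
        for _ in range(2):
            sol += np.linalg.solve(a, rhs - a @ sol)
    except np.linalg.LinAlgError as exc:
        raise DegenerateControlPointsError(f"TPS system singular: {exc}") from exc
    return ColorCorrectionMap(control_points=cap, weights=sol[:n],
                              affine=sol[n:], kernel=kernel, lam=lam)


def apply_map(cmap: ColorCorrectionMap, colors) -> np.ndarray:
    """Evaluate the fitted map on an (m, 3) array (or a single triple).

    Values are returned unclipped; clip to [0, 255] only at export.
    """
    x = np.atleast_2d(np.asarray(colors, dtype=float))
    u = _phi(cdist(x, cmap.control_points), cmap.kernel)
    out = cmap.affine[0] + x @ cmap.affine[1:] + u @ cmap.weights
    return out[0] if np.ndim(colors) == 1 else out


def correction_residual(cmap: ColorCorrectionMap, pairs) -> float:
    """Root-mean-square error of the map over color pairs, channels pooled."""
    cap, ref = _pair_arrays(pairs)
    if cap.shape[0] == 0:
        raise ValueError("empty pair list")
    err = apply_map(cmap, cap) - ref
    return float(np.sqrt(np.mean(err ** 2)))


# ---------------------------------------------------------------------------
# Diagonal (von Kries) white-balance baseline
# ---------------------------------------------------------------------------

def fit_diagonal_gains(pairs, white_id: str | None = None) -> np.ndarray:
    """Per-channel gains from the white (or brightest-reference) patch.

    The simple baseline the spline map is measured against: reference_white /
    captured_white, one scalar per channel.
    """
    cap, ref = _pair_arrays(pairs)
    if white_id is not None:
        ids = [p.entry_id for p in pairs]
        idx = ids.index(white_id)
    else:
        idx = int(np.argmax(ref.sum(axis=1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = np.where(cap[idx] > 0, ref[idx] / cap[idx], 1.0)
    return gains


def apply_diagonal_gains(gains: np.ndarray, colors) -> np.ndarray:
    return np.asarray(colors, dtype=float) * np.asarray(gains, dtype=float)
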