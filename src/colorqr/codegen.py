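"""Back-compatible Color QR code generation.

A Color QR code is a standard QR symbol in which selected data-region modules
are replaced by colorimetric reference patches.  Back-compatibility is
enforced structurally: each patch is placed only on a module whose binary
value matches the patch color's side of the mid-gray luminance threshold, so
grayscale binarization of the rendered symbol reproduces the original
black/white module matrix exactly and any standard decoder still reads the
payload.  The embedded patches then double as a color-constancy chart for
scene correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import qrcodec
from .qrcodec import CapacityError, function_pattern_map, matrix_side

__all__ = [
    "CapacityError",
    "matrix_side",
    "PaletteEntry",
    "ColorQRSpec",
    "ModuleMatrix",
    "ColorModuleMatrix",
    "PlacementError",
    "LuminanceConflictError",
    "encode_payload",
    "choose_placements",
    "embed_palette",
    "render_symbol",
    "relative_luminance",
    "load_palette",
    "save_palette",
    "default_palette",
]

#: binarization threshold on Rec.601 luminance; >= is "light"
LUMINANCE_THRESHOLD = 128.0


class PlacementError(ValueError):
    """A palette placement falls on a function pattern or outside the symbol."""


class LuminanceConflictError(ValueError):
    """A palette color's luminance side conflicts with the underlying module."""


def relative_luminance(rgb) -> float:
    r, g, b = rgb
    return 0.299 * r + 0.587 * g + 0.114 * b


@dataclass(frozen=True)
class PaletteEntry:
    """One colorimetric reference patch: label + its reference-condition RGB."""

    id: str
    reference_rgb: tuple[int, int, int]

    def __post_init__(self):
        if len(self.reference_rgb) != 3 or not all(0 <= v <= 255 for v in self.reference_rgb):
            raise ValueError(f"reference_rgb must be in [0,255]^3, got {self.reference_rgb}")

    @property
    def is_dark(self) -> bool:
        return relative_luminance(self.reference_rgb) < LUMINANCE_THRESHOLD


@dataclass
class ModuleMatrix:
    """Binary module grid of a standard QR symbol (True = dark)."""

    cells: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=bool)
        side = self.cells.shape[0]
        if self.cells.ndim != 2 or self.cells.shape[1] != side or (side - 17) % 4:
            raise ValueError(f"not a QR module grid: shape {self.cells.shape}")

    @property
    def side(self) -> int:
        return self.cells.shape[0]

    @property
    def version(self) -> int:
        return (self.side - 17) // 4


@dataclass
class ColorModuleMatrix:
    """Colored module grid plus the palette placement index."""

    cells: np.ndarray                                  # side x side x 3 uint8
    placement_index: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def side(self) -> int:
        return self.cells.shape[0]


@dataclass
class ColorQRSpec:
    """Complete recipe for one Color QR code.

    ``placements`` lists the (row, col) module coordinates of the palette
    patches, one per palette entry, 0-based from the top-left corner in
    image row-major order.  When omitted, placements are chosen greedily
    row-major over the data region, matching each entry's luminance side.
    """

    payload: str
    version: int = 3
    ec_level: str = "Q"
    palette: list[PaletteEntry] = field(default_factory=list)
    placements: list[tuple[int, int]] | None = None
    module_px: int = 10
    quiet_zone: int = 4

    @property
    def qr_id(self) -> str:
        return self.payload.split("#", 1)[1] if "#" in self.payload else ""

    def resolved_placements(self, matrix: ModuleMatrix | None = None) -> list[tuple[int, int]]:
        if self.placements is not None:
            return list(self.placements)
        if matrix is None:
            matrix = encode_payload(self.payload, self.version, self.ec_level)
        return choose_placements(matrix, self.palette)


def encode_payload(payload: str, version: int = 3, ec_level: str = "Q") -> ModuleMatrix:
    """Encode a payload into the final (masked) module matrix of a symbol.

    Raises :class:`~colorqr.qrcodec.CapacityError` naming version, EC level
    and payload length when the payload does not fit.
    """
    return ModuleMatrix(qrcodec.encode(payload, version, ec_level))


def choose_placements(matrix: ModuleMatrix, palette: list[PaletteEntry]) -> list[tuple[int, int]]:
    """Assign palette entries to data-region modules, greedily row-major.

    Each entry is placed on the next unused data module whose binary value
    matches the entry's luminance side, keeping binarization (and hence
    standard decoding) intact without spending error-correction budget.
    """
    is_function, _ = function_pattern_map(matrix.version)
    side = matrix.side
    used: set[tuple[int, int]] = set()
    placements = []
    for entry in palette:
        want_dark = entry.is_dark
        for r in range(side):
            for c in range(side):
                if is_function[r, c] or (r, c) in used:
                    continue
                if bool(matrix.cells[r, c]) == want_dark:
                    placements.append((r, c))
                    used.add((r, c))
                    break
            else:
                continue
            break
        else:
            raise LuminanceConflictError(
                f"no free {'dark' if want_dark else 'light'} data module left "
                f"for palette entry {entry.id!r}"
            )
    return placements


def embed_palette(matrix: ModuleMatrix, palette: list[PaletteEntry],
                  placements: list[tuple[int, int]]) -> ColorModuleMatrix:
    """Replace the modules at ``placements`` by the palette reference colors.

    Every non-palette cell stays pure black or pure white; each palette cell
    must binarize to the same side as the underlying module, otherwise a
    :class:`LuminanceConflictError` is raised.
    """
    if len(palette) != len(placements):
        raise ValueError(f"{len(palette)} palette entries but {len(placements)} placements")
    if len(set(placements)) != len(placements):
        raise PlacementError("duplicate placements")
    side = matrix.side
    is_function, _ = function_pattern_map(matrix.version)
    cells = np.where(matrix.cells[..., None], [0, 0, 0], [255, 255, 255]).astype(np.uint8)
    index: dict[tuple[int, int], str] = {}
    for entry, (r, c) in zip(palette, placements):
        if not (0 <= r < side and 0 <= c < side):
            raise PlacementError(f"placement ({r},{c}) outside the {side}x{side} symbol")
        if is_function[r, c]:
            raise PlacementError(
                f"placement ({r},{c}) for entry {entry.id!r} falls on a function pattern"
            )
        if entry.is_dark != bool(matrix.cells[r, c]):
            raise LuminanceConflictError(
                f"entry {entry.id!r} (luminance "
                f"{relative_luminance(entry.reference_rgb):.1f}) conflicts with the "
                f"{'dark' if matrix.cells[r, c] else 'light'} module at ({r},{c})"
            )
        cells[r, c] = entry.reference_rgb
        index[(r, c)] = entry.id
    return ColorModuleMatrix(cells=cells, placement_index=index)


def render_symbol(colored: ColorModuleMatrix, module_px: int = 10,
                  quiet_zone: int = 4) -> np.ndarray:
    """Render a colored module matrix to an 8-bit RGB image.

    Output side length is ``(side + 2*quiet_zone) * module_px``; the quiet
    zone is white.  Rendering is lossless nearest-neighbour block expansion,
    so the center pixel of any module is exactly its cell color.
    """
    if module_px < 1:
        raise ValueError("module_px must be >= 1")
    side = colored.side
    canvas = np.full(((side + 2 * quiet_zone), (side + 2 * quiet_zone), 3), 255, dtype=np.uint8)
    canvas[quiet_zone:quiet_zone + side, quiet_zone:quiet_zone + side] = colored.cells
    return np.repeat(np.repeat(canvas, module_px, axis=0), module_px, axis=1)


# ---------------------------------------------------------------------------
# Palette I/O
# ---------------------------------------------------------------------------

def load_palette(source) -> list[PaletteEntry]:
    """Load a palette from a JSON file: ``[{"id": ..., "rgb": [r,g,b]}, ...]``."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = json.load(fh)
    else:
        raw = json.load(source)
    return [PaletteEntry(d["id"], tuple(d["rgb"])) for d in raw]


def save_palette(palette: list[PaletteEntry], path) -> None:
    with open(path, "w") as fh:
        json.dump([{"id": e.id, "rgb": list(e.reference_rgb)} for e in palette], fh, indent=1)


def default_palette(chemistry: str) -> list[PaletteEntry]:
    """Shipped 24-entry palette for a chemistry ("BTB" or "DPD").

    Both palettes combine a 6-step neutral ramp, an 8-step dye-response ramp
    (blue for the BTB strip, pink for the DPD cuvette), and 10 saturated
    anchors spanning RGB space so the thin-plate-spline correction is well
    conditioned in all three channels.  The numeric values are package
    constants, not measured chart colors.
    """
    name = {"BTB": "palette_btb.json", "DPD": "palette_dpd.json"}.get(chemistry.upper())
    if name is None:
        raise ValueError(f"unknown chemistry {chemistry!r}; expected BTB or DPD")
    with resources.files("colorqr.data").joinpath(name).open() as fh:
        return load_palette(fh)
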