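"""Minimal QR symbol codec (model 2, versions 1-10, byte mode).

Implements the carrier layer that the colorimetric chart rides on: byte-mode
encoding, Reed-Solomon error correction over GF(256), mask selection by the
standard penalty rules, and format/version information.  A matrix decoder is
provided as an independent read path (format recovery, unmasking,
de-interleaving and error correction from the module grid alone) so that
rendered symbols can be verified by decoding rather than by construction.

Only byte mode is supported: the payloads carried here are short URLs with a
fragment identifier, which never benefit from numeric/alphanumeric modes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CapacityError",
    "QRDecodeError",
    "encode",
    "decode_matrix",
    "matrix_side",
    "data_capacity_bytes",
    "function_pattern_map",
]


class CapacityError(ValueError):
    """Payload does not fit the chosen version / error-correction level."""


class QRDecodeError(ValueError):
    """Module matrix could not be decoded as a QR symbol."""


# ---------------------------------------------------------------------------
# GF(256) arithmetic (primitive polynomial x^8+x^4+x^3+x^2+1 = 0x11D)
# ---------------------------------------------------------------------------

_GF_EXP = [0] * 512
_GF_LOG = [0] * 256
_x = 1
for _i in range(255):
    _GF_EXP[_i] = _x
    _GF_LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _GF_EXP[_i] = _GF_EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _GF_EXP[_GF_LOG[a] + _GF_LOG[b]]


def _gf_inv(a: int) -> int:
    return _GF_EXP[255 - _GF_LOG[a]]


def _poly_eval(poly: list[int], x: int) -> int:
    # Horner, poly[0] = highest-degree coefficient
    y = 0
    for c in poly:
        y = _gf_mul(y, x) ^ c
    return y


def _rs_generator(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        h = [0] * (len(g) + 1)
        for j, c in enumerate(g):
            h[j] ^= _gf_mul(c, 1)
            h[j + 1] ^= _gf_mul(c, _GF_EXP[i])
        g = h
    return g


def _rs_encode(data: list[int], nsym: int) -> list[int]:
    gen = _rs_generator(nsym)
    res = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = res[i]
        if coef:
            for j in range(1, len(gen)):
                res[i + j] ^= _gf_mul(gen[j], coef)
    return res[len(data):]


def _gf_solve(a: list[list[int]], b: list[int]) -> list[int] | None:
    """Gaussian elimination over GF(256); None if the system is singular."""
    n = len(b)
    m = [row[:] + [b[i]] for i, row in enumerate(a)]
    for col in range(n):
        piv = next((r for r in range(col, n) if m[r][col]), None)
        if piv is None:
            return None
        m[col], m[piv] = m[piv], m[col]
        inv = _gf_inv(m[col][col])
        m[col] = [_gf_mul(v, inv) for v in m[col]]
        for r in range(n):
            if r != col and m[r][col]:
                f = m[r][col]
                m[r] = [v ^ _gf_mul(f, m[col][k]) for k, v in enumerate(m[r])]
    return [m[i][n] for i in range(n)]


def _rs_correct(codeword: list[int], nsym: int) -> list[int]:
    """Correct up to nsym//2 errors (Peterson-Gorenstein-Zierler)."""
    n = len(codeword)
    synd = [_poly_eval(codeword, _GF_EXP[j]) for j in range(nsym)]
    if not any(synd):
        return codeword
    t = nsym // 2
    lam = None
    for nu in range(t, 0, -1):
        a = [[synd[nu + r - j] for j in range(1, nu + 1)] for r in range(nu)]
        b = [synd[nu + r] for r in range(nu)]
        sol = _gf_solve(a, b)
        if sol is not None:
            lam = [1] + sol  # Lambda(x) = 1 + l1 x + ... + l_nu x^nu
            break
    if lam is None:
        raise QRDecodeError("Reed-Solomon: error locator not solvable")
    nu = len(lam) - 1
    # Chien search over term degrees d: root at x = alpha^{-d}
    degrees = []
    for d in range(n):
        xinv = _GF_EXP[(255 - d) % 255]
        if _poly_eval(lam[::-1], xinv) == 0:
            degrees.append(d)
    if len(degrees) != nu:
        raise QRDecodeError("Reed-Solomon: wrong number of error locations")
    # magnitudes: S_j = sum_k e_k * alpha^{d_k * j}
    m = [[_GF_EXP[(d * j) % 255] for d in degrees] for j in range(nu)]
    mags = _gf_solve(m, synd[:nu])
    if mags is None:
        raise QRDecodeError("Reed-Solomon: magnitude system singular")
    out = codeword[:]
    for d, e in zip(degrees, mags):
        out[n - 1 - d] ^= e
    if any(_poly_eval(out, _GF_EXP[j]) for j in range(nsym)):
        raise QRDecodeError("Reed-Solomon: correction failed (too many errors)")
    return out


# ---------------------------------------------------------------------------
# Symbol structure tables (versions 1-10)
# ---------------------------------------------------------------------------

# (ec codewords per block, [(block count, data codewords per block), ...])
_EC_TABLE: dict[int, dict[str, tuple[int, list[tuple[int, int]]]]] = {
    1: {"L": (7, [(1, 19)]), "M": (10, [(1, 16)]), "Q": (13, [(1, 13)]), "H": (17, [(1, 9)])},
    2: {"L": (10, [(1, 34)]), "M": (16, [(1, 28)]), "Q": (22, [(1, 22)]), "H": (28, [(1, 16)])},
    3: {"L": (15, [(1, 55)]), "M": (26, [(1, 44)]), "Q": (18, [(2, 17)]), "H": (22, [(2, 13)])},
    4: {"L": (20, [(1, 80)]), "M": (18, [(2, 32)]), "Q": (26, [(2, 24)]), "H": (16, [(4, 9)])},
    5: {"L": (26, [(1, 108)]), "M": (24, [(2, 43)]), "Q": (18, [(2, 15), (2, 16)]), "H": (22, [(2, 11), (2, 12)])},
    6: {"L": (18, [(2, 68)]), "M": (16, [(4, 27)]), "Q": (24, [(4, 19)]), "H": (28, [(4, 15)])},
    7: {"L": (20, [(2, 78)]), "M": (18, [(4, 31)]), "Q": (18, [(2, 14), (4, 15)]), "H": (26, [(4, 13), (1, 14)])},
    8: {"L": (24, [(2, 97)]), "M": (22, [(2, 38), (2, 39)]), "Q": (22, [(4, 18), (2, 19)]), "H": (26, [(4, 14), (2, 15)])},
    9: {"L": (30, [(2, 116)]), "M": (22, [(3, 36), (2, 37)]), "Q": (20, [(4, 16), (4, 17)]), "H": (24, [(4, 12), (4, 13)])},
    10: {"L": (18, [(2, 68), (2, 69)]), "M": (26, [(4, 43), (1, 44)]), "Q": (24, [(6, 19), (2, 20)]), "H": (28, [(6, 15), (2, 16)])},
}

_REMAINDER_BITS = {1: 0, 2: 7, 3: 7, 4: 7, 5: 7, 6: 7, 7: 0, 8: 0, 9: 0, 10: 0}

_ALIGNMENT = {
    1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30], 6: [6, 34],
    7: [6, 22, 38], 8: [6, 24, 42], 9: [6, 26, 46], 10: [6, 28, 50],
}

_EC_BITS = {"L": 1, "M": 0, "Q": 3, "H": 2}
_EC_FROM_BITS = {v: k for k, v in _EC_BITS.items()}

_FORMAT_MASK = 0x5412
_FORMAT_GEN = 0x537     # BCH(15,5)
_VERSION_GEN = 0x1F25   # BCH(18,6)

_MASKS = [
    lambda r, c: (r + c) % 2 == 0,
    lambda r, c: r % 2 == 0,
    lambda r, c: c % 3 == 0,
    lambda r, c: (r + c) % 3 == 0,
    lambda r, c: (r // 2 + c // 3) % 2 == 0,
    lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
]


def matrix_side(version: int) -> int:
    """Module side length: 17 + 4*version."""
    if not 1 <= version <= 10:
        raise ValueError(f"supported symbol versions are 1-10, got {version}")
    return 17 + 4 * version


def data_capacity_bytes(version: int, ec_level: str) -> int:
    """Maximum byte-mode payload length for a version / EC level."""
    ec, blocks = _EC_TABLE[version][ec_level]
    data_cw = sum(n * k for n, k in blocks)
    count_bits = 16 if version >= 10 else 8
    return (data_cw * 8 - 4 - count_bits) // 8


def _bch_remainder(value: int, gen: int, gen_deg: int) -> int:
    v = value << gen_deg
    for shift in range(v.bit_length() - 1, gen_deg - 1, -1):
        if v >> shift & 1:
            v ^= gen << (shift - gen_deg)
    return v


def _format_value(ec_level: str, mask: int) -> int:
    data = (_EC_BITS[ec_level] << 3) | mask
    return ((data << 10) | _bch_remainder(data, _FORMAT_GEN, 10)) ^ _FORMAT_MASK


def _version_value(version: int) -> int:
    return (version << 12) | _bch_remainder(version, _VERSION_GEN, 12)


def _format_positions(side: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    vert, horiz = [], []
    for i in range(15):
        if i < 6:
            vert.append((i, 8))
        elif i < 8:
            vert.append((i + 1, 8))
        else:
            vert.append((side - 15 + i, 8))
        if i < 8:
            horiz.append((8, side - 1 - i))
        elif i == 8:
            horiz.append((8, 7))
        else:
            horiz.append((8, 14 - i))
    return vert, horiz


def function_pattern_map(version: int) -> tuple[np.ndarray, np.ndarray]:
    """(is_function, dark) maps for all function patterns and reserved areas.

    ``is_function`` marks every module that cannot carry data (finder,
    separator, timing, alignment, format/version information, dark module);
    ``dark`` gives the fixed module colors on those cells (format cells are
    filled in later, per mask).
    """
    side = matrix_side(version)
    isf = np.zeros((side, side), dtype=bool)
    dark = np.zeros((side, side), dtype=bool)

    def finder(r0: int, c0: int) -> None:
        for r in range(-1, 8):
            for c in range(-1, 8):
                rr, cc = r0 + r, c0 + c
                if 0 <= rr < side and 0 <= cc < side:
                    isf[rr, cc] = True
                    if 0 <= r <= 6 and 0 <= c <= 6:
                        dark[rr, cc] = r in (0, 6) or c in (0, 6) or (2 <= r <= 4 and 2 <= c <= 4)

    finder(0, 0)
    finder(0, side - 7)
    finder(side - 7, 0)

    for i in range(8, side - 8):
        for rc in ((6, i), (i, 6)):
            isf[rc] = True
            dark[rc] = i % 2 == 0

    centers = _ALIGNMENT[version]
    for cr in centers:
        for cc in centers:
            # the three combinations overlapping finder corners carry no pattern
            if (cr == 6 and cc == 6) or (cr == 6 and cc == centers[-1]) \
                    or (cr == centers[-1] and cc == 6):
                continue
            for r in range(-2, 3):
                for c in range(-2, 3):
                    isf[cr + r, cc + c] = True
                    dark[cr + r, cc + c] = max(abs(r), abs(c)) != 1

    for pos in _format_positions(side)[0] + _format_positions(side)[1]:
        isf[pos] = True
    isf[side - 8, 8] = True
    dark[side - 8, 8] = True  # the fixed dark module

    if version >= 7:
        for i in range(18):
            isf[i // 3, side - 11 + i % 3] = True
            isf[side - 11 + i % 3, i // 3] = True
    return isf, dark


def _data_coords(side: int, is_function: np.ndarray) -> list[tuple[int, int]]:
    coords = []
    inc = -1
    row = side - 1
    for col0 in range(side - 1, 0, -2):
        col = col0 - 1 if col0 <= 6 else col0
        while True:
            for c in (col, col - 1):
                if not is_function[row, c]:
                    coords.append((row, c))
            row += inc
            if row < 0 or row >= side:
                row -= inc
                inc = -inc
                break
    return coords


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _make_data_codewords(payload: bytes, version: int, ec_level: str) -> list[int]:
    ec, blocks = _EC_TABLE[version][ec_level]
    data_cw = sum(n * k for n, k in blocks)
    count_bits = 16 if version >= 10 else 8
    bits: list[int] = []

    def push(value: int, n: int) -> None:
        bits.extend((value >> (n - 1 - i)) & 1 for i in range(n))

    push(0b0100, 4)  # byte mode
    push(len(payload), count_bits)
    for byte in payload:
        push(byte, 8)
    if len(bits) > data_cw * 8:
        raise CapacityError(
            f"payload of {len(payload)} bytes exceeds capacity of version "
            f"{version}-{ec_level} ({data_capacity_bytes(version, ec_level)} bytes)"
        )
    bits.extend([0] * min(4, data_cw * 8 - len(bits)))  # terminator
    bits.extend([0] * (-len(bits) % 8))
    cw = [sum(b << (7 - i) for i, b in enumerate(bits[k:k + 8])) for k in range(0, len(bits), 8)]
    pad = (0xEC, 0x11)
    for i in range(data_cw - len(cw)):
        cw.append(pad[i % 2])
    return cw


def _block_structure(version: int, ec_level: str) -> tuple[int, list[int]]:
    ec, blocks = _EC_TABLE[version][ec_level]
    sizes = []
    for n, k in blocks:
        sizes.extend([k] * n)
    return ec, sizes


def _interleave(data_cw: list[int], version: int, ec_level: str) -> list[int]:
    ec, sizes = _block_structure(version, ec_level)
    data_blocks, pos = [], 0
    for k in sizes:
        data_blocks.append(data_cw[pos:pos + k])
        pos += k
    ec_blocks = [_rs_encode(b, ec) for b in data_blocks]
    out = []
    for i in range(max(sizes)):
        for b in data_blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(ec):
        for b in ec_blocks:
            out.append(b[i])
    return out


def _penalty(matrix: np.ndarray) -> int:
    side = matrix.shape[0]
    m = matrix.astype(np.int8)
    score = 0
    # rule 1: runs of >=5 in rows/cols
    for grid in (m, m.T):
        for row in grid:
            run = 1
            for i in range(1, side):
                if row[i] == row[i - 1]:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + run - 5
                    run = 1
            if run >= 5:
                score += 3 + run - 5
    # rule 2: 2x2 blocks
    same = (m[:-1, :-1] == m[1:, :-1]) & (m[:-1, :-1] == m[:-1, 1:]) & (m[:-1, :-1] == m[1:, 1:])
    score += 3 * int(same.sum())
    # rule 3: finder-like pattern with 4-module light run
    pat = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=np.int8)
    for grid in (m, m.T):
        for row in grid:
            for i in range(side - 10):
                win = row[i:i + 11]
                if np.array_equal(win, pat) or np.array_equal(win, pat[::-1]):
                    score += 40
    # rule 4: dark proportion
    dark_pct = 100.0 * m.sum() / (side * side)
    score += 10 * int(abs(dark_pct - 50) // 5)
    return score


def encode(payload: str | bytes, version: int = 3, ec_level: str = "H",
           mask: int | None = None) -> np.ndarray:
    """Encode a byte-mode payload into a boolean module matrix (True = dark).

    When ``mask`` is None the mask with the lowest standard penalty score is
    selected; a fixed mask 0-7 can be forced for testing.
    """
    if ec_level not in _EC_BITS:
        raise ValueError(f"EC level must be one of L,M,Q,H, got {ec_level!r}")
    side = matrix_side(version)
    data = payload.encode("utf-8") if isinstance(payload, str) else bytes(payload)
    codewords = _interleave(_make_data_codewords(data, version, ec_level), version, ec_level)

    bits = []
    for cw in codewords:
        bits.extend((cw >> (7 - i)) & 1 for i in range(8))
    bits.extend([0] * _REMAINDER_BITS[version])

    isf, fixed = function_pattern_map(version)
    coords = _data_coords(side, isf)
    if len(coords) != len(bits):
        raise AssertionError("internal: data area size mismatch")

    candidates = range(8) if mask is None else [mask]
    best, best_score = None, None
    for mk in candidates:
        mat = fixed.copy()
        mfun = _MASKS[mk]
        for (r, c), bit in zip(coords, bits):
            mat[r, c] = bool(bit) ^ mfun(r, c)
        fmt = _format_value(ec_level, mk)
        vert, horiz = _format_positions(side)
        for i in range(15):
            mat[vert[i]] = bool(fmt >> i & 1)
            mat[horiz[i]] = bool(fmt >> i & 1)
        if version >= 7:
            vv = _version_value(version)
            for i in range(18):
                bit = bool(vv >> i & 1)
                mat[i // 3, side - 11 + i % 3] = bit
                mat[side - 11 + i % 3, i // 3] = bit
        score = _penalty(mat) if mask is None else 0
        if best_score is None or score < best_score:
            best, best_score = mat, score
    return best


# ---------------------------------------------------------------------------
# Decoding (from a sampled module matrix)
# ---------------------------------------------------------------------------

_ALL_FORMATS = {(_EC_FROM_BITS[e], mk): _format_value(lvl, mk)
                for lvl, e in _EC_BITS.items() for mk in range(8)
                for e in [_EC_BITS[lvl]]}


def _read_format(matrix: np.ndarray) -> tuple[str, int]:
    side = matrix.shape[0]
    vert, horiz = _format_positions(side)
    best = None
    for positions in (vert, horiz):
        raw = 0
        for i, pos in enumerate(positions):
            raw |= int(bool(matrix[pos])) << i
        for (lvl, mk), val in _ALL_FORMATS.items():
            dist = bin(raw ^ val).count("1")
            if best is None or dist < best[0]:
                best = (dist, lvl, mk)
    if best is None or best[0] > 3:
        raise QRDecodeError("format information unreadable")
    return best[1], best[2]


def decode_matrix(matrix: np.ndarray) -> str:
    """Decode a boolean module matrix (True = dark) back to its payload.

    Reads the format information, unmasks, de-interleaves the codeword
    stream, applies Reed-Solomon correction per block and parses the
    byte-mode bit stream.
    """
    matrix = np.asarray(matrix, dtype=bool)
    side = matrix.shape[0]
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1] or (side - 17) % 4:
        raise QRDecodeError(f"matrix shape {matrix.shape} is not a QR symbol")
    version = (side - 17) // 4
    if not 1 <= version <= 10:
        raise QRDecodeError(f"unsupported symbol version {version}")

    ec_level, mk = _read_format(matrix)
    isf, _ = function_pattern_map(version)
    mfun = _MASKS[mk]
    bits = [int(matrix[r, c]) ^ int(mfun(r, c)) for r, c in _data_coords(side, isf)]

    n_cw = len(bits) // 8
    codewords = [sum(b << (7 - i) for i, b in enumerate(bits[k * 8:k * 8 + 8])) for k in range(n_cw)]

    ec, sizes = _block_structure(version, ec_level)
    nblocks = len(sizes)
    data_blocks: list[list[int]] = [[] for _ in range(nblocks)]
    ec_blocks: list[list[int]] = [[] for _ in range(nblocks)]
    it = iter(codewords)
    for i in range(max(sizes)):
        for b in range(nblocks):
            if i < sizes[b]:
                data_blocks[b].append(next(it))
    for _ in range(ec):
        for b in range(nblocks):
            ec_blocks[b].append(next(it))

    data: list[int] = []
    for b in range(nblocks):
        corrected = _rs_correct(data_blocks[b] + ec_blocks[b], ec)
        data.extend(corrected[:sizes[b]])

    # parse byte-mode stream
    stream = []
    for cw in data:
        stream.extend((cw >> (7 - i)) & 1 for i in range(8))
    pos = 0

    def take(n: int) -> int:
        nonlocal pos
        v = 0
        for _ in range(n):
            v = (v << 1) | stream[pos]
            pos += 1
        return v

    out = bytearray()
    count_bits = 16 if version >= 10 else 8
    while pos + 4 <= len(stream):
        mode = take(4)
        if mode == 0:
            break
        if mode != 0b0100:
            raise QRDecodeError(f"unsupported mode indicator {mode:04b}")
        n = take(count_bits)
        if pos + 8 * n > len(stream):
            raise QRDecodeError("byte segment overruns data stream")
        for _ in range(n):
            out.append(take(8))
    try:
        return out.decode("utf-8")
    except UnicodeDecodeError:
        return out.decode("latin-1")
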