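"""Arithmetic over GF(2⁸) with the standard primitive polynomial 0x11D.

Log/antilog tables are built once at import; polynomial helpers operate on
coefficient lists with the highest-degree coefficient first.
"""

from __future__ import annotations

import numpy as np

from .core import ArgumentError

PRIMITIVE_POLY = 0x11D
FIELD_SIZE = 256


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    exp = np.zeros(512, dtype=np.int64)
    log = np.zeros(256, dtype=np.int64)
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x <<= 1
        if x & 0x100:
            x ^= PRIMITIVE_POLY
    exp[255:510] = exp[0:255]  # wraparound so exp[(a+b)] needs no mod
    return exp, log


GF_EXP, GF_LOG = _build_tables()


def gf_add(a: int, b: int) -> int:
    """Addition = subtraction = XOR in characteristic 2."""
    return a ^ b


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(GF_EXP[GF_LOG[a] + GF_LOG[b]])


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ArgumentError("division by zero in GF(256)")
    if a == 0:
        return 0
    return int(GF_EXP[(GF_LOG[a] - GF_LOG[b]) % 255])


def gf_pow(a: int, n: int) -> int:
    if a == 0:
        if n == 0:
            return 1
        if n < 0:
            raise ArgumentError("zero to a negative power in GF(256)")
        return 0
    return int(GF_EXP[(GF_LOG[a] * n) % 255])


def gf_inverse(a: int) -> int:
    return gf_div(1, a)


def clmul_mod(a: int, b: int, poly: int = PRIMITIVE_POLY) -> int:
    """Carry-less polynomial multiply of a and b, reduced mod poly.

    Independent bitwise route used to cross-check the table-based product.
    """
    result = 0
    while b:
        if b & 1:
            result ^= a
        b >>= 1
        a <<= 1
        if a & 0x100:
            a ^= poly
    return result


# -- polynomials, coefficient lists with highest degree first --------------


def poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi == 0:
            continue
        for j, qj in enumerate(q):
            out[i + j] ^= gf_mul(pi, qj)
    return out


def poly_add(p: list[int], q: list[int]) -> list[int]:
    n = max(len(p), len(q))
    out = [0] * n
    out[n - len(p) :] = p
    for i, qi in enumerate(q):
        out[n - len(q) + i] ^= qi
    return out


def poly_eval(p: list[int], x: int) -> int:
    """Horner evaluation of p at x."""
    y = 0
    for coef in p:
        y = gf_mul(y, x) ^ coef
    return y


def poly_scale(p: list[int], s: int) -> list[int]:
    return [gf_mul(c, s) for c in p]


def poly_interpolate(xs: list[int], ys: list[int]) -> list[int]:
    """Lagrange interpolation: the unique poly of degree < len(xs)."""
    if len(xs) != len(ys) or len(set(xs)) != len(xs):
        raise ArgumentError("interpolation needs distinct x of matching length")
    result = [0]
    for i, (xi, yi) in enumerate(zip(xs, ys)):
        term = [1]
        denom = 1
        for j, xj in enumerate(xs):
            if j == i:
                continue
            term = poly_mul(term, [1, xj])  # (x - xj) == (x + xj)
            denom = gf_mul(denom, xi ^ xj)
        term = poly_scale(term, gf_div(yi, denom))
        result = poly_add(result, term)
    return result
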