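"""Systematic Reed–Solomon coding over GF(256).

Codewords of length n ≤ 255 with nsym = n − k parity symbols, generator
roots α⁰..α^{nsym−1}.  The decoder handles errors and erasures jointly:
with e errors and f erasures, decoding succeeds when 2e + f ≤ nsym.
Used both as the inner code of the reference codec (error correction
within a sequence) and as its outer code (erasure recovery across
sequences), and as the error-detection check of the fountain codec.
"""

from __future__ import annotations

from .core import OligobenchError
from .gf256 import GF_EXP, GF_LOG, gf_div, gf_inverse, gf_mul, gf_pow, poly_eval, poly_mul


class RSDecodeError(OligobenchError):
    """Uncorrectable codeword."""


def rs_generator_poly(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = poly_mul(g, [1, gf_pow(2, i)])
    return g


def rs_encode(msg: bytes | list[int], nsym: int) -> bytes:
    """Append nsym parity symbols (systematic encoding)."""
    msg = list(msg)
    if len(msg) + nsym > 255:
        raise OligobenchError("RS codeword length exceeds 255")
    gen = rs_generator_poly(nsym)
    rem = msg + [0] * nsym
    for i in range(len(msg)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return bytes(msg + rem[len(msg) :])


def rs_syndromes(codeword: bytes | list[int], nsym: int) -> list[int]:
    word = list(codeword)
    return [poly_eval(word, gf_pow(2, i)) for i in range(nsym)]


def rs_check(codeword: bytes | list[int], nsym: int) -> bool:
    """True when all syndromes vanish (no detectable error)."""
    return not any(rs_syndromes(codeword, nsym))


def _erasure_locator(coef_positions: list[int]) -> list[int]:
    loc = [1]
    for pos in coef_positions:
        loc = poly_mul(loc, [gf_pow(2, pos), 1])
    return loc


def _berlekamp_massey(syndromes: list[int]) -> list[int]:
    """Error locator polynomial from (Forney) syndromes."""
    err_loc = [1]
    old_loc = [1]
    for i in range(len(syndromes)):
        delta = syndromes[i]
        for j in range(1, len(err_loc)):
            delta ^= gf_mul(err_loc[-(j + 1)], syndromes[i - j])
        old_loc.append(0)
        if delta:
            if len(old_loc) > len(err_loc):
                new_loc = [gf_mul(c, delta) for c in old_loc]
                old_loc = [gf_div(c, delta) for c in err_loc]
                err_loc = new_loc
            err_loc = [0] * (len(old_loc) - len(err_loc)) + err_loc
            for j in range(len(old_loc)):
                err_loc[-(j + 1)] ^= gf_mul(delta, old_loc[-(j + 1)])
    while err_loc and err_loc[0] == 0:
        err_loc.pop(0)
    return err_loc


def _find_error_positions(err_loc: list[int], n: int) -> list[int]:
    """Chien search; returns coefficient positions (from the right)."""
    n_errors = len(err_loc) - 1
    positions = []
    for i in range(n):
        if poly_eval(err_loc, gf_pow(2, -i)) == 0:
            positions.append(i)
    if len(positions) != n_errors:
        raise RSDecodeError("error locator does not factor over the field")
    return positions


def _forney_syndromes(
    syndromes: list[int], coef_positions: list[int], nsym: int
) -> list[int]:
    fsynd = list(syndromes)
    for pos in coef_positions:
        x = gf_pow(2, pos)
        for i in range(len(fsynd) - 1):
            fsynd[i] = gf_mul(fsynd[i], x) ^ fsynd[i + 1]
        fsynd.pop()
    return fsynd


def rs_decode(
    codeword: bytes | list[int], nsym: int, erase_pos: list[int] | None = None
) -> tuple[bytes, int]:
    """Correct a codeword in place; returns (message, symbols corrected).

    ``erase_pos`` are array positions (0 = leftmost symbol) known to be
    unreliable.  Raises :class:`RSDecodeError` when the codeword is
    uncorrectable (2·errors + erasures > nsym, or an inconsistent
    locator/syndrome state is detected).
    """
    word = list(codeword)
    n = len(word)
    erase_pos = sorted(set(erase_pos or []))
    if len(erase_pos) > nsym:
        raise RSDecodeError(f"{len(erase_pos)} erasures exceed nsym={nsym}")
    coef_erase = [n - 1 - p for p in erase_pos]

    synd = rs_syndromes(word, nsym)
    if not any(synd):
        return bytes(word[: n - nsym]), 0

    fsynd = _forney_syndromes(synd, coef_erase, nsym)
    err_loc = _berlekamp_massey(fsynd)
    n_errors = len(err_loc) - 1
    if 2 * n_errors + len(coef_erase) > nsym:
        raise RSDecodeError("too many errors for the parity budget")
    coef_errors = _find_error_positions(err_loc, n)

    all_coef = coef_erase + [p for p in coef_errors if p not in coef_erase]
    loc = _erasure_locator(all_coef)
    # error evaluator omega = synd * loc mod x^nsym
    synd_poly = list(reversed(synd))
    omega_full = poly_mul(synd_poly, loc)
    omega = omega_full[len(omega_full) - nsym :]

    # formal derivative of the locator (characteristic 2: odd terms only)
    loc_rev = list(reversed(loc))
    deriv_rev = [loc_rev[i] if i % 2 == 1 else 0 for i in range(1, len(loc_rev))]
    deriv = list(reversed(deriv_rev))

    for pos in all_coef:
        x_inv = gf_pow(2, -pos)
        num = poly_eval(omega, x_inv)
        den = poly_eval(deriv, x_inv)
        if den == 0:
            raise RSDecodeError("Forney denominator vanished")
        magnitude = gf_mul(gf_pow(2, pos), gf_div(num, den))
        word[n - 1 - pos] ^= magnitude

    if any(rs_syndromes(word, nsym)):
        raise RSDecodeError("residual syndromes after correction")
    return bytes(word[: n - nsym]), len(all_coef)
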