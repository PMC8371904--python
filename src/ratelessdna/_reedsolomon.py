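"""Reed-Solomon codec over GF(2^8).

Systematic RS with a freely configurable number of parity bytes, used as the
strongest of the packet checksum options: up to floor(nsym/2) byte errors in
a packet are corrected before the packet is accepted; anything beyond that
surfaces as an integrity failure (an erasure).

Field: GF(2^8) with primitive polynomial 0x11D, generator element 2, first
consecutive root exponent 0 — the ubiquitous convention.  The decoder is the
textbook chain: syndromes -> Berlekamp-Massey error locator -> Chien search
-> Forney error magnitudes.  Polynomials are coefficient lists with the
highest degree first.
"""

from __future__ import annotations

from .errors import IntegrityError, ParameterError

_PRIM = 0x11D

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def _mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("GF(2^8) division by zero")
    if a == 0:
        return 0
    return _EXP[(_LOG[a] - _LOG[b]) % 255]


def _inverse(a: int) -> int:
    return _EXP[255 - _LOG[a]]


def _pow(a: int, power: int) -> int:
    return _EXP[(_LOG[a] * power) % 255]


def _poly_scale(p: list[int], x: int) -> list[int]:
    return [_mul(c, x) for c in p]


def _poly_add(p: list[int], q: list[int]) -> list[int]:
    out = [0] * max(len(p), len(q))
    out[len(out) - len(p):] = p
    for i, c in enumerate(q):
        out[i + len(out) - len(q)] ^= c
    return out


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi:
            for j, qj in enumerate(q):
                out[i + j] ^= _mul(pi, qj)
    return out


def _poly_div(dividend: list[int], divisor: list[int]) -> tuple[list[int], list[int]]:
    out = list(dividend)
    for i in range(len(dividend) - (len(divisor) - 1)):
        coef = out[i]
        if coef:
            for j in range(1, len(divisor)):
                if divisor[j]:
                    out[i + j] ^= _mul(divisor[j], coef)
    sep = -(len(divisor) - 1)
    return out[:sep], out[sep:]


def _poly_eval(p: list[int], x: int) -> int:
    y = p[0]
    for c in p[1:]:
        y = _mul(y, x) ^ c
    return y


def _generator_poly(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, _pow(2, i)])
    return g


def rs_encode(data: bytes, nsym: int) -> bytes:
    """Parity bytes for ``data``; codeword = data + parity (systematic)."""
    if nsym < 1:
        raise ParameterError("rs_encode requires nsym >= 1")
    if len(data) + nsym > 255:
        raise ParameterError("RS codeword longer than 255 bytes")
    gen = _generator_poly(nsym)
    _, remainder = _poly_div(list(data) + [0] * nsym, gen)
    return bytes(remainder)


def _syndromes(msg: list[int], nsym: int) -> list[int]:
    # leading 0 pad keeps the Berlekamp-Massey shift arithmetic simple
    return [0] + [_poly_eval(msg, _pow(2, i)) for i in range(nsym)]


def _error_locator(synd: list[int], nsym: int) -> list[int]:
    err_loc = [1]
    old_loc = [1]
    synd_shift = len(synd) - nsym
    for i in range(nsym):
        k = i + synd_shift
        delta = synd[k]
        for j in range(1, len(err_loc)):
            delta ^= _mul(err_loc[-(j + 1)], synd[k - j])
        old_loc = old_loc + [0]
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = _poly_scale(old_loc, delta)
                old_loc = _poly_scale(err_loc, _inverse(delta))
                err_loc = new_loc
            err_loc = _poly_add(err_loc, _poly_scale(old_loc, delta))
    while len(err_loc) and err_loc[0] == 0:
        del err_loc[0]
    errs = len(err_loc) - 1
    if errs * 2 > nsym:
        raise IntegrityError("Reed-Solomon: too many errors to correct")
    return err_loc


def _find_errors(err_loc: list[int], nmess: int) -> list[int]:
    errs = len(err_loc) - 1
    err_pos = []
    for i in range(nmess):
        if _poly_eval(err_loc, _pow(2, i)) == 0:
            err_pos.append(nmess - 1 - i)
    if len(err_pos) != errs:
        raise IntegrityError("Reed-Solomon: error locator is degenerate")
    return err_pos


def _errata_locator(coef_pos: list[int]) -> list[int]:
    e_loc = [1]
    for i in coef_pos:
        e_loc = _poly_mul(e_loc, _poly_add([1], [_pow(2, i), 0]))
    return e_loc


def _error_evaluator(synd: list[int], err_loc: list[int], nsym: int) -> list[int]:
    _, remainder = _poly_div(_poly_mul(synd, err_loc), [1] + [0] * (nsym + 1))
    return remainder


def _correct_errata(msg: list[int], synd: list[int], err_pos: list[int]) -> list[int]:
    coef_pos = [len(msg) - 1 - p for p in err_pos]
    err_loc = _errata_locator(coef_pos)
    err_eval = _error_evaluator(synd[::-1], err_loc, len(err_loc) - 1)[::-1]

    x_vals = [_pow(2, -(255 - c)) for c in coef_pos]
    magnitudes = [0] * len(msg)
    for i, xi in enumerate(x_vals):
        xi_inv = _inverse(xi)
        err_loc_prime = 1
        for j, xj in enumerate(x_vals):
            if j != i:
                err_loc_prime = _mul(err_loc_prime, 1 ^ _mul(xi_inv, xj))
        if err_loc_prime == 0:
            raise IntegrityError("Reed-Solomon: Forney derivative vanished")
        y = _poly_eval(err_eval[::-1], xi_inv)
        y = _mul(_pow(xi, 1), y)  # first consecutive root exponent is 0
        magnitudes[err_pos[i]] = _div(y, err_loc_prime)
    return _poly_add(msg, magnitudes)


def rs_decode(codeword: bytes, nsym: int) -> bytes:
    """Correct up to floor(nsym/2) byte errors; return the data part.

    Raises :class:`IntegrityError` when the error pattern exceeds the
    correction radius (the caller then treats the packet as erased).
    """
    if len(codeword) > 255:
        raise ParameterError("RS codeword longer than 255 bytes")
    if len(codeword) <= nsym:
        raise ParameterError("RS codeword shorter than its parity")
    msg = list(codeword)
    synd = _syndromes(msg, nsym)
    if max(synd) == 0:
        return codeword[:-nsym]
    err_loc = _error_locator(synd, nsym)
    err_pos = _find_errors(err_loc[::-1], len(msg))
    corrected = _correct_errata(msg, synd, err_pos)
    if max(_syndromes(corrected, nsym)) != 0:
        raise IntegrityError("Reed-Solomon: correction failed")
    return bytes(corrected[:-nsym])
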