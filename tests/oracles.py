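"""Independent extended-precision transcriptions of the thermal-time formulas.

These are deliberately written from the piecewise definitions using the
stdlib ``decimal`` module at 50 significant digits (powers via exp·ln),
sharing no code with the numpy implementation they cross-check.
"""

from decimal import Decimal, getcontext

getcontext().prec = 50

ZERO = Decimal(0)


def _dec(*xs):
    return tuple(Decimal(x) for x in xs)


def dtt_method1_oracle(t_max, t_min, t_b, t_u) -> Decimal:
    tmax, tmin, tb, tu = _dec(t_max, t_min, t_b, t_u)
    tavg = (tmax + tmin) / 2
    if tavg < tb:
        return ZERO
    if tavg > tu:
        return tu - tb
    return tavg - tb


def dtt_method2_oracle(t_max, t_min, t_b, t_u) -> Decimal:
    tmax, tmin, tb, tu = _dec(t_max, t_min, t_b, t_u)
    tavg = (tmax + tmin) / 2
    if tavg < tb:
        return ZERO
    if tavg > tu:
        return tu - tb
    tm = min(tmax, tu)
    tn = max(tmin, tb)
    return (tm + tn) / 2 - tb


def htt_method3_oracle(t_h, t_b, t_opt, t_u) -> Decimal:
    th, tb, to, tu = _dec(t_h, t_b, t_opt, t_u)
    if th < tb or th > tu:
        return ZERO
    if th <= to:
        return th - tb
    return (to - tb) / (tu - to) * (tu - th)


def beta_shape_oracle(t_h, t_b, t_opt, t_u) -> Decimal:
    th, tb, to, tu = _dec(t_h, t_b, t_opt, t_u)
    if th < tb or th > tu:
        return ZERO
    if th == tu:
        return ZERO
    rise = (th - tb) / (to - tb)
    fall = (tu - th) / (tu - to)
    exponent = (tu - to) / (to - tb)
    if rise == 0:
        return ZERO
    return rise * (exponent * fall.ln()).exp()


def htt_bfm_oracle(t_h, t_b, t_opt, t_u) -> Decimal:
    th, tb, to, tu = _dec(t_h, t_b, t_opt, t_u)
    return beta_shape_oracle(t_h, t_b, t_opt, t_u) * (to - tb)
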