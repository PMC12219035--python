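"""Independent reference computations used to check the package.

Everything here is deliberately written as a separate route from the library
code: the formula oracle re-derives each effective lens position step by step
and finds the predicted refraction by numeric root-finding on the *forward*
thin-lens vergence chain (spectacle plane → cornea → lens plane → retina),
instead of the library's closed-form algebraic inversions. Metric oracles are
plain Python loops.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq


def vergence_chain_residual(
    ref_spectacle: float,
    iol_power: float,
    elp_mm: float,
    optical_length_mm: float,
    corneal_power_d: float,
    vertex_mm: float,
    n_media: float = 1.336,
) -> float:
    """Residual of the forward vergence chain at a candidate refraction.

    Positive-direction bookkeeping: a spectacle correction ``ref_spectacle``
    is moved to the corneal plane, the cornea adds its power, the vergence is
    propagated ``elp_mm`` into the eye, the IOL adds its power, and the
    result must focus on the retina at ``optical_length_mm``.
    """
    rc = ref_spectacle / (1.0 - (vertex_mm / 1000.0) * ref_spectacle)
    u = corneal_power_d + rc
    v1 = 1000.0 * n_media / (1000.0 * n_media / u - elp_mm)
    return (v1 + iol_power) - 1000.0 * n_media / (optical_length_mm - elp_mm)


def _solve(residual) -> float:
    return brentq(residual, -40.0, 40.0, xtol=1e-12)


def srkt_refraction(al, km, iol_power, a_const=119.082, vertex=12.0):
    r = 337.5 / km
    lcor = al if al <= 24.2 else -3.446 + 1.715 * al - 0.0237 * al**2
    cw = -5.41 + 0.58412 * lcor + 0.098 * km
    h = r - math.sqrt(max(r * r - cw * cw / 4.0, 0.0))
    elp = h + (0.62467 * a_const - 68.747) - 3.336
    lopt = al + 0.65696 - 0.02029 * al
    dc = 1000.0 * 0.333 / r
    return _solve(lambda x: vergence_chain_residual(x, iol_power, elp, lopt, dc, vertex))


def holladay1_refraction(al, km, iol_power, sf=1.860, vertex=12.0):
    r = 337.5 / km
    ag = min(al * 12.5 / 23.45, 13.5)
    elp = 0.56 + r - math.sqrt(max(r * r - ag * ag / 4.0, 0.0)) + sf
    lopt = al + 0.2
    dc = 1000.0 * (1.0 / 3.0) / r
    return _solve(lambda x: vergence_chain_residual(x, iol_power, elp, lopt, dc, vertex))


def hofferq_refraction(al, km, iol_power, pacd=5.727, vertex=12.0):
    alc = min(max(al, 18.5), 31.0)
    m, g = (1.0, 28.0) if alc <= 23.0 else (-1.0, 23.5)
    tan = lambda deg: math.tan(math.radians(deg))
    elp = (
        pacd
        + 0.3 * (alc - 23.5)
        + tan(km) ** 2
        + 0.1 * m * (23.5 - alc) ** 2 * tan(0.1 * (g - alc) ** 2)
        - 0.99166
    )
    # Hoffer's chain measures both distances 0.05 mm behind the lens plane
    # and keeps the keratometric power as the corneal power.
    return _solve(
        lambda x: vergence_chain_residual(x, iol_power, elp + 0.05, al, km, vertex)
    )


def haigis_refraction(al, acd, km, iol_power, a0=-0.739, a1=0.4, a2=0.1, vertex=12.0):
    r = 337.5 / km
    dc = 1000.0 * (1.3315 - 1.0) / r
    elp = a0 + a1 * acd + a2 * al
    return _solve(lambda x: vergence_chain_residual(x, iol_power, elp, al, dc, vertex))


ORACLES = {
    "SRKT": lambda al, km, acd, p, c, v=12.0: srkt_refraction(al, km, p, c, v),
    "HofferQ": lambda al, km, acd, p, c, v=12.0: hofferq_refraction(al, km, p, c, v),
    "Holladay1": lambda al, km, acd, p, c, v=12.0: holladay1_refraction(al, km, p, c, v),
    "Haigis": lambda al, km, acd, p, c, v=12.0: haigis_refraction(al, acd, km, p, c, 0.4, 0.1, v),
}


def loop_summary(errors) -> dict:
    """Loop-based error summary (the library uses vectorized numpy)."""
    n = len(errors)
    me = sum(errors) / n
    mae = sum(abs(e) for e in errors) / n
    srt = sorted(abs(e) for e in errors)
    med = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2.0
    rmsae = math.sqrt(sum(e * e for e in errors) / n)
    sd = math.sqrt(sum((e - me) ** 2 for e in errors) / (n - 1)) if n > 1 else 0.0
    return {"ME": me, "MAE": mae, "MedAE": med, "RMSAE": rmsae, "SD": sd}


def friedman_statistic_no_ties(matrix) -> float:
    """Friedman chi-square from the textbook rank formula (assumes no ties)."""
    n = len(matrix)
    k = len(matrix[0])
    col_rank_sums = [0.0] * k
    for row in matrix:
        order = sorted(range(k), key=lambda j: row[j])
        for rank0, j in enumerate(order):
            col_rank_sums[j] += rank0 + 1
    return 12.0 / (n * k * (k + 1)) * sum(r * r for r in col_rank_sums) - 3.0 * n * (k + 1)
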