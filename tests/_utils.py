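"""Shared independent oracles and helpers for the test suite.

Everything here deliberately avoids the package's own code paths so that
implementation and oracle stay independent.
"""

import itertools
import math

import numpy as np

from budclock.synthetic_data import SimulationConfig


def small_config(**overrides):
    """A scaled-down simulation config for fast repeated runs."""
    base = dict(
        n_coupled=20,
        n_housekeeping=10,
        n_switch=10,
        n_peak=5,
        n_background=150,
        n_low=10,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def uncoupled_config(**overrides):
    """Config in which no gene class depends on date or temperature."""
    base = dict(
        coupling_beta=0.0,
        n_switch=0,
        n_peak=0,
        n_coupled=30,
        n_housekeeping=10,
        n_background=200,
        n_low=20,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# Spearman oracles
# ---------------------------------------------------------------------------


def brute_force_ranks(values):
    """Average (mid) ranks computed by explicit pairwise comparison."""
    values = list(values)
    ranks = []
    for x in values:
        less = sum(1 for y in values if y < x)
        equal = sum(1 for y in values if y == x)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def brute_force_spearman(x, y):
    """Rank both vectors by brute force, then apply the Pearson formula."""
    rx = brute_force_ranks(x)
    ry = brute_force_ranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def exact_permutation_p(x, y):
    """Two-sided exact permutation p for tie-free vectors (n <= 7).

    Enumerates all n! assignments of y ranks and uses the tie-free identity
    rho = 1 - 6*sum(d^2)/(n*(n^2-1)).
    """
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    denom = n * (n * n - 1)
    rho_obs = 1.0 - 6.0 * np.sum((rx - ry) ** 2) / denom
    perms = np.array(list(itertools.permutations(range(1, n + 1))))
    rhos = 1.0 - 6.0 * np.sum((perms - rx[None, :]) ** 2, axis=1) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)), float(rho_obs)


# ---------------------------------------------------------------------------
# day-length oracle: full solar-position computation (apparent ecliptic
# longitude and true obliquity), independent of the package's simpler
# Fourier declination model
# ---------------------------------------------------------------------------


def solar_position_daylength(date, lat_deg):
    jd = date.toordinal() + 1721424.5 + 0.5  # local noon
    T = (jd - 2451545.0) / 36525.0
    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T * T) % 360
    M = math.radians(357.52911 + 35999.05029 * T - 0.0001537 * T * T)
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T * T) * math.sin(M)
        + (0.019993 - 0.000101 * T) * math.sin(2 * M)
        + 0.000289 * math.sin(3 * M)
    )
    omega = math.radians(125.04 - 1934.136 * T)
    app_long = L0 + C - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = (
        23 + 26 / 60 + 21.448 / 3600
        - (46.815 * T + 0.00059 * T * T - 0.001813 * T**3) / 3600
    )
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(eps) * math.sin(math.radians(app_long)))
    lat = math.radians(lat_deg)
    cos_h = (math.sin(math.radians(-0.833)) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    cos_h = max(-1.0, min(1.0, cos_h))
    return 2.0 * math.degrees(math.acos(cos_h)) / 15.0
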