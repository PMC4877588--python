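"""Independent reference implementations used as test oracles.

These deliberately avoid the library's code paths: the circuit oracle
solves the node-voltage linear system directly with a dense solve, the
dispersion oracle is an explicit Python loop, and the t-test oracle is
the textbook formula evaluated step by step.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def nodal_transfer_ratio(impedances, gel_index, v_in=1.0 + 0j):
    """Voltage across element ``gel_index`` of a series chain, per volt
    input, from a direct Kirchhoff node-voltage solve."""
    z = [complex(zz) for zz in impedances]
    n = len(z)
    # nodes 0..n; node 0 driven at v_in, node n grounded; KCL at 1..n-1
    A = np.zeros((n - 1, n - 1), dtype=complex)
    b = np.zeros(n - 1, dtype=complex)
    for k in range(n - 1):
        A[k, k] = 1 / z[k] + 1 / z[k + 1]
        if k > 0:
            A[k, k - 1] = -1 / z[k]
        if k < n - 2:
            A[k, k + 1] = -1 / z[k + 1]
    b[0] = v_in / z[0]
    internal = np.linalg.solve(A, b)
    volts = np.concatenate([[v_in], internal, [0.0 + 0j]])
    return (volts[gel_index] - volts[gel_index + 1]) / v_in


def mesh_transfer_ratio(impedances, gel_index, v_in=1.0 + 0j):
    """Single-loop mesh solve: loop current from the total impedance
    accumulated by explicit complex addition, gel voltage from Ohm's law."""
    total = 0.0 + 0j
    for z in impedances:
        total = total + complex(z)
    current = v_in / total
    return current * complex(impedances[gel_index]) / v_in


def loop_center(points):
    """Arithmetic-mean centroid via explicit accumulation."""
    sx = sy = sz = 0.0
    n = 0
    for x, y, z in points:
        sx += x
        sy += y
        sz += z
        n += 1
    return (sx / n, sy / n, sz / n)


def loop_dispersion(points):
    """Population RMS 3D distance from the centroid, via explicit loops."""
    cx, cy, cz = loop_center(points)
    total = 0.0
    n = 0
    for x, y, z in points:
        total += (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        n += 1
    return math.sqrt(total / n)


def hand_pooled_t(a, b):
    """Pooled-variance two-sample t-test from the textbook formula."""
    a = list(a)
    b = list(b)
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def hand_welch_t(a, b):
    """Welch t statistic and Satterthwaite df from the textbook formula."""
    a = list(a)
    b = list(b)
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p
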