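"""Independent scalar-loop reimplementation of one model step.

Written directly from the model equations with plain Python loops and no
shared code with the package's vectorised implementation; used to pin the
array arithmetic term by term.
"""

from __future__ import annotations


def scalar_pins(a, n, p):
    """Quasi-steady PIN1 allocation per cell: (p_left, p_right) lists."""
    N = len(a)
    p_left, p_right = [], []
    for i in range(N):
        al = a[(i - 1) % N]
        ar = a[(i + 1) % N]
        denom = al + ar
        p_left.append(n * p * al / denom)
        p_right.append(n * p * ar / denom)
    return p_left, p_right


def scalar_rates(a, params):
    """Per-cell da/dt from synthesis, turnover, PIN transport, diffusion."""
    N = len(a)
    n, p = params.n, params.p
    rates = []
    for i in range(N):
        il, ir = (i - 1) % N, (i + 1) % N
        al, ar = a[il], a[ir]
        p_left = n * p * al / (al + ar)
        p_right = n * p * ar / (al + ar)
        # membranes of the two neighbours that face cell i
        p_from_left = n * p * a[i] / (a[(il - 1) % N] + a[i])
        p_from_right = n * p * a[i] / (a[i] + a[(ir + 1) % N])
        transport = a[i] * (p_left + p_right) - p_from_left * al \
            - p_from_right * ar
        diffusion = al + ar - 2.0 * a[i]
        rates.append(params.A - params.G_a * a[i]
                     - params.E_p * transport + params.D_a * diffusion)
    return rates


def scalar_euler_step(a, params):
    """One forward-Euler auxin update; returns (new_a, rates)."""
    rates = scalar_rates(a, params)
    return [a[i] + params.dt * rates[i] for i in range(len(a))], rates
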