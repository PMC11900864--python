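"""Independent naive transcriptions of the filter recursions.

These are deliberately written as literal, step-by-step plain-Python
loops, independent of the package's vectorized/stateful implementations,
and serve as oracles in equivalence tests.
"""

import math

EPS = 1e-8


def _sig(x):
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _clip(p):
    return min(max(p, EPS), 1.0 - EPS)


def naive_hgf(u, omega=-3.0, mu2=0.0, sigma2=1.0, mode="canonical"):
    pi2 = 1.0 / sigma2
    out = []
    for ut in u:
        s = _clip(_sig(mu2))
        if mode == "canonical":
            pi_hat = 1.0 / (1.0 / pi2 + math.exp(omega))
        else:
            pi_hat = pi2
        pi2 = pi_hat + s * (1.0 - s)
        mu2 = mu2 + (ut - s) / pi2
        out.append((s, mu2, pi2))
    return out


def naive_rw(u, alpha, v=0.5):
    out = []
    for ut in u:
        s = _clip(v)
        v = v + alpha * (ut - v)
        out.append((s, v))
    return out


def naive_k1(u, mu_k1, beta=math.log(0.1), v=0.5):
    h = 0.0
    out = []
    for ut in u:
        s = _clip(v)
        delta = ut - v
        beta = beta + mu_k1 * delta * h
        k = math.exp(beta)
        v = min(max(v + k * delta, EPS), 1.0 - EPS)
        h = h * max(0.0, 1.0 - k) + k * delta
        out.append((s, v))
    return out


def naive_ph(u, eta, kappa, assoc=1.0, v=0.5):
    out = []
    for ut in u:
        s = _clip(v)
        delta = ut - v
        v = v + kappa * assoc * delta
        assoc = eta * abs(delta) + (1.0 - eta) * assoc
        out.append((s, v))
    return out
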