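"""Independent, deliberately naive reference implementations.

Everything here is written from the defining formulas with plain Python
loops (O(N^2) DFT included) so the vectorized library code can be checked
against an implementation that shares none of its pathways.
"""

import cmath
import math


def mean_oracle(x):
    return sum(x) / len(x)


def std_oracle(x):
    m = mean_oracle(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def kurtosis_printed_oracle(x):
    m = mean_oracle(x)
    m4 = sum((v - m) ** 4 for v in x) / len(x)
    return m4 / std_oracle(x) ** 2 - 3.0


def kurtosis_standard_oracle(x):
    m = mean_oracle(x)
    m4 = sum((v - m) ** 4 for v in x) / len(x)
    return m4 / std_oracle(x) ** 4 - 3.0


def crest_oracle(x):
    rms = math.sqrt(sum(v * v for v in x) / len(x))
    return max(x) / rms


def pearson_oracle(x, y):
    n = len(x)
    mx, my = mean_oracle(x), mean_oracle(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    return cov / (std_oracle(x) * std_oracle(y))


def corr_printed_oracle(x, y):
    n = len(x)
    cross = sum(a * b for a, b in zip(x, y)) / n
    return (cross - mean_oracle(x) * mean_oracle(y)) / (std_oracle(x) * std_oracle(y))


def dft_amplitudes_oracle(x):
    """One-sided magnitudes, DC excluded, K = floor(N/2) lines; O(N^2)."""
    n = len(x)
    out = []
    for k in range(1, n // 2 + 1):
        s = sum(x[j] * cmath.exp(-2j * math.pi * k * j / n) for j in range(n))
        out.append(abs(s))
    return out


def energy_oracle(a):
    return sum(v * v for v in a) / len(a)


def entropy_oracle(a):
    total = sum(a)
    if total == 0:
        return 0.0
    ent = 0.0
    for v in a:
        if v > 0:
            p = v / total
            ent -= p * math.log2(p)
    return ent
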