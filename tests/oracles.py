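"""Independent reference computations used by the test suite."""

import math


def exact_binomial_tail(alt: int, depth: int, p: float) -> float:
    """P[Binomial(depth, p) >= alt] by direct log-space term summation.

    Independent of scipy: each term comes from lgamma, summed until the
    remaining tail is negligible relative to the running maximum.
    """
    if alt <= 0:
        return 1.0
    if p <= 0.0:
        return 0.0
    lp, lq = math.log(p), math.log1p(-p)
    log_terms: list[float] = []
    mode = depth * p
    for k in range(alt, depth + 1):
        lt = (
            math.lgamma(depth + 1)
            - math.lgamma(k + 1)
            - math.lgamma(depth - k + 1)
            + k * lp
            + (depth - k) * lq
        )
        log_terms.append(lt)
        if k > mode and lt < max(log_terms) - 60.0:
            break
    m = max(log_terms)
    return math.exp(m) * sum(math.exp(t - m) for t in log_terms)
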