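"""Shared test utilities."""

import numpy as np
from scipy.special import kolmogorov


def discrete_ks_pvalue(samples, cdf) -> float:
    """One-sample KS test of integer-valued data against a discrete CDF.

    The statistic is the supremum of |ECDF - F| over the integer support;
    both step functions are right-continuous and constant between integers,
    so evaluating at every integer in the observed range is exact.  The
    Kolmogorov asymptotic p-value is conservative for discrete nulls
    (the true null distribution of D is stochastically smaller).
    """
    samples = np.asarray(samples)
    n = len(samples)
    vals = np.arange(samples.min() - 1, samples.max() + 1)
    ecdf = np.searchsorted(np.sort(samples), vals, side="right") / n
    d = np.abs(ecdf - np.asarray(cdf(vals))).max()
    return float(kolmogorov(np.sqrt(n) * d))
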