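"""Independent numerical oracles shared by the test modules."""

import numpy as np

from quorumsignal import transition_rates


def absorption_oracle(U, V, p):
    """Fixation probability of one U mutant by first-step analysis.

    Builds the explicit (Z+1)-state birth-death chain from the one-step
    rates and solves the linear absorption equations, independently of the
    closed-form product expression.
    """
    Z = p.Z
    a = np.zeros(Z + 1)
    b = np.zeros(Z + 1)
    for k in range(1, Z):
        r = transition_rates(U, V, k, p)
        a[k], b[k] = r.t_plus, r.t_minus
    # x_k = a_k x_{k+1} + b_k x_{k-1} + (1 - a_k - b_k) x_k, x_0 = 0, x_Z = 1
    A = np.zeros((Z + 1, Z + 1))
    rhs = np.zeros(Z + 1)
    A[0, 0] = 1.0
    A[Z, Z] = 1.0
    rhs[Z] = 1.0
    for k in range(1, Z):
        A[k, k] = a[k] + b[k]
        A[k, k + 1] = -a[k]
        A[k, k - 1] = -b[k]
    return np.linalg.solve(A, rhs)[1]
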