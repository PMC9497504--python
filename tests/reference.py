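"""Literal double-loop reference implementations used as test oracles.

Deliberately scalar and naive: plain ``math`` over explicit loops, no
shared code with the vectorized package implementation.
"""

import math


def ref_pair_prob(Z, tau, i, j):
    num = math.exp(sum(a * b for a, b in zip(Z[i], Z[j])) / tau)
    den = sum(
        math.exp(sum(a * b for a, b in zip(Z[i], Z[k])) / tau)
        for k in range(len(Z))
        if k != i
    )
    return num / den


def _log1m(p):
    # the negative-pair contract clamps p at 1 - 1e-12 before log(1 - p)
    return math.log(max(1.0 - p, 1e-12))


def ref_losses(Z, y, tau, eta, gamma):
    """Literal sums over anchors: returns (CL, FCL, ACL, AFCL)."""
    n = len(Z)
    cl = fcl = acl = afcl = 0.0
    for i in range(n):
        P = [j for j in range(n) if j != i and y[j] == y[i]]
        N = [j for j in range(n) if j != i and y[j] != y[i]]
        lp_cl = sum(math.log(ref_pair_prob(Z, tau, i, j)) for j in P) / len(P) if P else 0.0
        lp_f = (
            sum(
                (1 - ref_pair_prob(Z, tau, i, j)) * math.log(ref_pair_prob(Z, tau, i, j))
                for j in P
            )
            / len(P)
            if P
            else 0.0
        )
        lp_af = (
            sum(
                (1 - ref_pair_prob(Z, tau, i, j)) ** gamma
                * math.log(ref_pair_prob(Z, tau, i, j))
                for j in P
            )
            / len(P)
            if P
            else 0.0
        )
        ln = (
            sum(_log1m(ref_pair_prob(Z, tau, i, j)) for j in N) / len(N)
            if N
            else 0.0
        )
        cl += -lp_cl
        fcl += -lp_f
        acl += -(lp_cl + eta * ln)
        afcl += -(lp_af + eta * ln)
    return cl, fcl, acl, afcl


def ref_confusion(pred, true):
    tp = tn = fp = fn = 0
    for p, t in zip(pred, true):
        if p == 1 and t == 1:
            tp += 1
        elif p == 0 and t == 0:
            tn += 1
        elif p == 1 and t == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn
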