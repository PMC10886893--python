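"""Independent reference implementations used to cross-check the decoder.

These deliberately share no code with :mod:`motioncue.decode`: the Bayes
classifier works in the quadratic (Mahalanobis) form with per-class solves,
and the cross-validation oracle enumerates every held-out triple instead of
sampling them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def gaussian_bayes_fit(X, y, shrinkage=0.0):
    """Pooled-covariance Gaussian Bayes classifier, brute-force form."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    means, scatters, n_total = {}, [], len(y)
    for c in classes:
        Xc = X[y == c]
        means[c] = Xc.mean(axis=0)
        d = Xc - means[c]
        scatters.append(d.T @ d)
    cov = np.sum(scatters, axis=0) / (n_total - len(classes))
    if shrinkage > 0:
        p = X.shape[1]
        scale = np.trace(cov) / p
        if scale <= 0:
            scale = 1.0
        cov = (1 - shrinkage) * cov + shrinkage * scale * np.eye(p)
    return classes, means, cov


def gaussian_bayes_predict(model, X):
    """Argmax of -0.5 (x-mu)' Sigma^-1 (x-mu) (uniform priors, shared cov);
    ties go to the lowest class index (first maximum)."""
    classes, means, cov = model
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = np.empty((X.shape[0], len(classes)))
    for j, c in enumerate(classes):
        d = X - means[c]
        scores[:, j] = -0.5 * np.einsum("ip,ip->i", d, np.linalg.solve(cov, d.T).T)
    return classes[np.argmax(scores, axis=1)]


def enumerate_leave_three_out(
    X, y, n_train_veps, avg_size, shrinkage, rng, draws_per_triple=40
):
    """Expected hold-3-out accuracy by exhaustive enumeration of test triples.

    For every class and every possible held-out triple, the test VEP is the
    triple's mean; expected accuracy is averaged over ``draws_per_triple``
    random training-set draws (training VEPs are averages of ``avg_size``
    distinct trials from each class's pool, the test triple excluded from
    its own class only).  Returns (accuracy, n_decisions).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    pools = {c: X[y == c] for c in classes}
    correct = total = 0
    for c in classes:
        pool = pools[c]
        for triple in combinations(range(pool.shape[0]), 3):
            test_vep = pool[list(triple)].mean(axis=0)
            mask = np.ones(pool.shape[0], dtype=bool)
            mask[list(triple)] = False
            for _ in range(draws_per_triple):
                train_X, train_y = [], []
                for k in classes:
                    avail = pool[mask] if k == c else pools[k]
                    for _ in range(n_train_veps):
                        idx = rng.choice(avail.shape[0], size=avg_size, replace=False)
                        train_X.append(avail[idx].mean(axis=0))
                        train_y.append(k)
                model = gaussian_bayes_fit(
                    np.asarray(train_X), np.asarray(train_y), shrinkage
                )
                pred = gaussian_bayes_predict(model, test_vep)[0]
                correct += int(pred == c)
                total += 1
    return correct / total, total
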