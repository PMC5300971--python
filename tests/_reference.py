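"""Independent, unoptimised reference implementations used as oracles."""

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.cluster import kmeans_plusplus


def naive_em_gaussian(X, K, seed, max_iter=500, tol=1e-10, reg=1e-6):
    """Plain EM for a full-covariance Gaussian mixture, written directly
    from the textbook update equations (scipy densities, python loops).

    Starts from the same k-means++ centers protocol as the implementation
    under test so both descend the same likelihood surface; every EM
    quantity is computed independently. Returns the final total loglik.
    """
    n, d = X.shape
    ridge = reg * np.trace(np.cov(X.T)) / d
    centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed)
    assign = np.argmin(
        [[np.sum((x - c) ** 2) for c in centers] for x in X], axis=1
    )
    resp = np.zeros((n, K))
    resp[np.arange(n), assign] = 1.0

    loglik = -np.inf
    for _ in range(max_iter):
        nk = resp.sum(axis=0)
        weights = nk / n
        means = np.array([resp[:, k] @ X / nk[k] for k in range(K)])
        covs = []
        for k in range(K):
            Xc = X - means[k]
            covs.append((Xc.T * resp[:, k]) @ Xc / nk[k] + ridge * np.eye(d))
        dens = np.column_stack(
            [
                weights[k] * multivariate_normal.pdf(X, means[k], covs[k])
                for k in range(K)
            ]
        )
        total = dens.sum(axis=1)
        new_loglik = float(np.log(total).sum())
        resp = dens / total[:, None]
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    return loglik
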