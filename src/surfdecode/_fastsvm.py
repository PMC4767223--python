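"""Thin wrapper over scikit-learn's low-level libsvm binding.

``SVC(kernel="precomputed")`` and this wrapper run the identical libsvm
C-SVC solver; the wrapper skips the estimator's per-call parameter
validation, which dominates runtime when a permutation test refits the
same small problem hundreds of thousands of times. Agreement with the
public ``SVC`` estimator is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import _libsvm as libsvm

# match SVC defaults
_TOL = 1e-3
_CACHE_MB = 200.0

libsvm.set_verbosity_wrap(0)  # silence the solver's per-fit chatter


def svm_decision_gram(
    G_train: np.ndarray,
    y_train: np.ndarray,
    K_test: np.ndarray,
    c_param: float = 1.0,
) -> np.ndarray:
    """Decision values (sklearn sign convention: positive -> class 1)
    for test rows of a precomputed linear kernel.

    ``G_train`` is the train x train Gram matrix, ``K_test`` the
    test x train kernel block; ``y_train`` must be 0/1 labels.
    """
    ytr = np.ascontiguousarray(y_train, dtype=np.float64)
    out = libsvm.fit(
        np.ascontiguousarray(G_train, dtype=np.float64),
        ytr,
        svm_type=0,
        kernel="precomputed",
        C=c_param,
        tol=_TOL,
        cache_size=_CACHE_MB,
    )
    support, _, _, sv_coef, intercept = out[0], out[1], out[2], out[3], out[4]
    dec = K_test[:, support] @ sv_coef[0] + intercept[0]
    # libsvm's raw binary decision value is the negative of sklearn's
    return -dec


def svm_predict_gram(
    G_train: np.ndarray,
    y_train: np.ndarray,
    K_test: np.ndarray,
    c_param: float = 1.0,
) -> np.ndarray:
    """Predicted 0/1 labels for test rows of a precomputed kernel."""
    dec = svm_decision_gram(G_train, y_train, K_test, c_param)
    return (dec > 0).astype(np.int64)
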