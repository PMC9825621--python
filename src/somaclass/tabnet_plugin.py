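"""Optional attentive deep tabular backend (requires pytorch-tabnet + torch).

The default architecture follows the published configuration: n_d=24,
n_a=24, n_steps=4, gamma=1.5, n_independent=2, n_shared=2,
lambda_sparse=1e-4, momentum=0.3, clip_value=2; Adam at lr 0.02, 100
epochs, batch 4000, virtual batch 256, with epoch selection by validation
average precision.
"""

from __future__ import annotations

from typing import Mapping

try:
    import torch
    from pytorch_tabnet.tab_model import TabNetClassifier
except ImportError as exc:  # pragma: no cover - optional dependency
    raise ImportError(
        "the tabnet_like backend requires the optional dependencies "
        "'pytorch-tabnet' and 'torch' (pip install somaclass[tabnet])"
    ) from exc

_ARCH_DEFAULTS = dict(
    n_d=24,
    n_a=24,
    n_steps=4,
    gamma=1.5,
    n_independent=2,
    n_shared=2,
    lambda_sparse=1e-4,
    momentum=0.3,
    clip_value=2,
)

_FIT_DEFAULTS = dict(
    max_epochs=100,
    patience=100,
    batch_size=4000,
    virtual_batch_size=256,
    eval_metric=["auc"],
)


class TabNetBackend:
    """scikit-learn-ish facade over TabNetClassifier with the published setup."""

    def __init__(self, hyperparameters: Mapping | None, seed: int):
        params = dict(_ARCH_DEFAULTS)
        fit_params = dict(_FIT_DEFAULTS)
        for k, v in (hyperparameters or {}).items():
            (fit_params if k in fit_params else params)[k] = v
        self._fit_params = fit_params
        self._clf = TabNetClassifier(
            seed=seed,
            optimizer_fn=torch.optim.Adam,
            optimizer_params=dict(lr=0.02),
            verbose=0,
            **params,
        )
        self.classes_ = [0, 1]

    def fit(self, X, y):
        self._clf.fit(X, y, **self._fit_params)
        return self

    def predict_proba(self, X):
        return self._clf.predict_proba(X)


def make_tabnet(hyperparameters: Mapping | None, seed: int) -> TabNetBackend:
    return TabNetBackend(hyperparameters, seed)
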