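"""Scikit-learn-style estimator facade over the segmentation pipeline.

`ACRNetSegmenter` wraps architecture construction, Tversky-loss training,
and (optionally test-time-augmented) prediction behind the familiar
fit/predict/score surface, so the model composes with sklearn tooling
(`clone`, `get_params`/`set_params`, pipelines, grid search).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .acrnet import ACRNet, ACRNetConfig, count_parameters
from .inference import predict_compound, predict_single
from .preprocess import GrayscaleSlice
from .training import TrainConfig, TverskyParams, evaluate_dsc, train


class ACRNetSegmenter(BaseEstimator):
    """Binary tumor segmenter built on the attention-condenser residual net.

    Parameters
    ----------
    stage_widths : tuple of int
        Encoder channel widths (decoder mirrors them).
    units_per_stage : int
        Residual units per encoder stage.
    condenser_ratio : int
        Channel bottleneck divisor of each attention condenser.
    input_size : (int, int)
        Spatial size the network consumes; training arrays must match.
    learning_rate, epochs, batch_size
        Adam optimiser settings for :meth:`fit`.
    alpha, beta, epsilon
        Tversky loss weights (FP penalty, FN penalty, stabilizer).
    threshold : float
        Probability cut for binarizing predictions (ties -> tumor).
    tta : bool
        If True, :meth:`predict` fuses the 8 dihedral copies by majority
        vote (compound decision); otherwise a single forward pass.
    random_state : int
        Seeds weight init, batch shuffling, and everything downstream.

    Attributes
    ----------
    model_ : ACRNet
        The trained network.
    history_ : list of dict
        Per-epoch log (epoch, loss, val_dsc, seconds).
    n_parameters_ : int
        Trainable scalar count of the instantiated network.
    """

    def __init__(self, stage_widths=(16, 32, 64), units_per_stage=1,
                 condenser_ratio=2, input_size=(64, 64),
                 learning_rate=1e-4, epochs=10, batch_size=4,
                 alpha=0.25, beta=0.75, epsilon=1e-8,
                 threshold=0.5, tta=True, random_state=0):
        self.stage_widths = stage_widths
        self.units_per_stage = units_per_stage
        self.condenser_ratio = condenser_ratio
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.alpha = alpha
        self.beta = beta
        self.epsilon = epsilon
        self.threshold = threshold
        self.tta = tta
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_arrays(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != tuple(self.input_size):
            raise ValueError(
                f"X must be (n, {self.input_size[0]}, {self.input_size[1]}), "
                f"got {X.shape}")
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} != X shape {X.shape}")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary masks")
        return X, y.astype(np.float64)

    def _build(self) -> ACRNet:
        cfg = ACRNetConfig(input_size=tuple(self.input_size),
                           stage_widths=tuple(self.stage_widths),
                           units_per_stage=self.units_per_stage,
                           condenser_ratio=self.condenser_ratio,
                           seed=self.random_state)
        return ACRNet(cfg)

    # ------------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on normalized slices X (n, H, W) and binary masks y."""
        X, y = self._validate_arrays(X, y)
        self.model_ = self._build()
        self.n_parameters_ = count_parameters(self.model_)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           epochs=self.epochs, batch_size=self.batch_size,
                           seed=self.random_state)
        params = TverskyParams(alpha=self.alpha, beta=self.beta,
                               epsilon=self.epsilon)
        self.history_ = train(self.model_, X, y,
                              val_images=X_val, val_masks=y_val,
                              tcfg=tcfg, params=params)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel tumor probabilities, shape (n, H, W)."""
        self._check_fitted()
        X = self._validate_arrays(X)
        out = np.empty_like(X)
        for start in range(0, len(X), max(1, self.batch_size)):
            batch = X[start:start + max(1, self.batch_size)]
            out[start:start + len(batch)] = \
                self.model_.forward(batch[:, None])[:, 0]
        return out

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, H, W); with ``tta`` uses compound decision."""
        self._check_fitted()
        X = self._validate_arrays(X)
        preds = np.empty(X.shape, dtype=np.uint8)
        for i, img in enumerate(X):
            slc = GrayscaleSlice(img)
            mask = (predict_compound(self.model_, slc, self.threshold)
                    if self.tta else
                    predict_single(self.model_, slc, self.threshold))
            preds[i] = mask.pixels
        return preds

    def score(self, X, y) -> float:
        """Mean per-slice Dice similarity coefficient."""
        self._check_fitted()
        X, y = self._validate_arrays(X, y)
        preds = self.predict(X)
        from .evaluation import evaluate_pair
        from .preprocess import BinaryMask
        scores = [evaluate_pair(BinaryMask(p), BinaryMask(q.astype(np.uint8))).dsc
                  for p, q in zip(preds, y)]
        return float(np.mean(scores))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
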