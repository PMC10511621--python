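"""Scikit-learn style estimators wrapping the patchwork pipeline.

``PatchworkSegmenter`` is the user-facing entry point: ``fit`` trains the
per-level networks on a list of (image, mask) subjects (or a
``PhantomCohort``), ``predict`` segments new volumes, ``score`` returns
the mean combined Dice.  Parameters follow sklearn conventions
(``get_params`` / ``set_params`` / ``clone`` compatible; fitted state in
trailing-underscore attributes).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .grid import LabelMask, VolumeGrid
from .inference import InferenceConfig, predict_volume
from .metrics import dice
from .model import DNPConfig, PatchworkModel, UNetConfig
from .pyramid import PatchPyramidConfig
from .trainer import TrainConfig, train

__all__ = ["PatchworkSegmenter", "SingleLevelSegmenter"]


class PatchworkSegmenter(BaseEstimator):
    """Hierarchical coarse-to-fine patchwork segmenter.

    Parameters mirror the pyramid geometry (``n_levels``, ``matrix``,
    ``coarsest_fov_mm``, ``finest_spacing_mm``), the per-level U-Net
    (``feature_dims``, ``decoder_kernel``), training (``learning_rate``,
    ``batch_size``, ``n_patches``, ``label_bias``, ``topk_fraction``) and
    branching inference (``n_candidates``, ``n_keep``, ``n_passes``,
    ``threshold``, ``inference_mode``).

    Examples
    --------
    >>> seg = PatchworkSegmenter(n_patches=2000, random_state=0)
    >>> seg.fit([(image, mask)])                        # doctest: +SKIP
    >>> predicted = seg.predict(image)                  # doctest: +SKIP
    """

    def __init__(
        self,
        n_levels: int = 3,
        matrix: int = 32,
        coarsest_fov_mm: float = 150.0,
        finest_spacing_mm: float = 1.0,
        feature_dims: tuple[int, ...] = (4, 8, 16, 32),
        convs_per_block: int = 1,
        decoder_kernel: int = 1,
        learning_rate: float = 0.001,
        batch_size: int = 16,
        n_patches: int = 20_000,
        label_bias: float = 0.8,
        topk_fraction: float = 0.1,
        validation: bool = True,
        n_candidates: int = 6,
        n_keep: int = 3,
        n_passes: int = 64,
        threshold: float = 0.5,
        inference_mode: str = "branching",
        overlap_stride_mm: float = 16.0,
        random_state: int = 0,
    ):
        self.n_levels = n_levels
        self.matrix = matrix
        self.coarsest_fov_mm = coarsest_fov_mm
        self.finest_spacing_mm = finest_spacing_mm
        self.feature_dims = feature_dims
        self.convs_per_block = convs_per_block
        self.decoder_kernel = decoder_kernel
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_patches = n_patches
        self.label_bias = label_bias
        self.topk_fraction = topk_fraction
        self.validation = validation
        self.n_candidates = n_candidates
        self.n_keep = n_keep
        self.n_passes = n_passes
        self.threshold = threshold
        self.inference_mode = inference_mode
        self.overlap_stride_mm = overlap_stride_mm
        self.random_state = random_state

    # ---- config assembly ----

    def _dnp_config(self) -> DNPConfig:
        return DNPConfig(
            pyramid=PatchPyramidConfig(
                n_levels=self.n_levels,
                matrix=self.matrix,
                coarsest_fov_mm=self.coarsest_fov_mm,
                finest_spacing_mm=self.finest_spacing_mm,
            ),
            unet=UNetConfig(
                feature_dims=tuple(self.feature_dims),
                convs_per_block=self.convs_per_block,
                matrix=self.matrix,
                decoder_kernel=self.decoder_kernel,
            ),
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            n_patches=self.n_patches,
            label_bias=self.label_bias,
            topk_fraction=self.topk_fraction,
            validation=self.validation,
            seed=self.random_state,
        )

    def _inference_config(self, mode: str | None = None) -> InferenceConfig:
        return InferenceConfig(
            n_candidates=self.n_candidates,
            n_keep=self.n_keep,
            n_passes=self.n_passes,
            threshold=self.threshold,
            mode=mode or self.inference_mode,
            overlap_stride_mm=self.overlap_stride_mm,
            seed=self.random_state,
        )

    # ---- estimator API ----

    def fit(self, X, y=None) -> "PatchworkSegmenter":
        """Train on subjects: a PhantomCohort or a list of (image, mask) pairs."""
        model = PatchworkModel(self._dnp_config(), seed=self.random_state)
        result = train(model, X, self._train_config())
        self.model_ = result.model
        self.log_ = result.log
        self.best_val_dice_ = result.best_val_dice
        self.n_levels_ = model.n_levels
        return self

    def predict(self, X, mode: str | None = None):
        """Segment one volume or a list of volumes into label masks."""
        self._check_fitted()
        single = isinstance(X, VolumeGrid)
        vols = [X] if single else list(X)
        cfg = self._inference_config(mode)
        masks = [predict_volume(self.model_, v, cfg).mask for v in vols]
        return masks[0] if single else masks

    def predict_proba(self, X, mode: str | None = None):
        """Per-class probability field(s) on the input grid."""
        self._check_fitted()
        single = isinstance(X, VolumeGrid)
        vols = [X] if single else list(X)
        cfg = self._inference_config(mode)
        probs = [predict_volume(self.model_, v, cfg).prob for v in vols]
        return probs[0] if single else probs

    def score(self, X, y) -> float:
        """Mean combined-foreground Dice over subjects."""
        masks = self.predict(X)
        if isinstance(masks, LabelMask):
            masks, y = [masks], [y]
        return float(np.mean([dice(m.data > 0, ref.data > 0) for m, ref in zip(masks, y)]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("this segmenter has not been fitted yet")


class SingleLevelSegmenter(PatchworkSegmenter):
    """Classical one-level 3D U-Net baseline (coarse 32^3 patch by default).

    Geometry defaults to the coarsest patchwork level only: a single
    150 mm field-of-view patch at 32^3, i.e. 4.6875 mm voxels — the
    hierarchy-free reference the patchwork is compared against.
    """

    def __init__(
        self,
        n_levels: int = 1,
        matrix: int = 32,
        coarsest_fov_mm: float = 150.0,
        finest_spacing_mm: float = 1.0,
        feature_dims: tuple[int, ...] = (4, 8, 16, 32),
        convs_per_block: int = 1,
        decoder_kernel: int = 1,
        learning_rate: float = 0.001,
        batch_size: int = 16,
        n_patches: int = 20_000,
        label_bias: float = 0.8,
        topk_fraction: float = 0.1,
        validation: bool = True,
        n_candidates: int = 6,
        n_keep: int = 3,
        n_passes: int = 64,
        threshold: float = 0.5,
        inference_mode: str = "branching",
        overlap_stride_mm: float = 16.0,
        random_state: int = 0,
    ):
        super().__init__(
            n_levels=n_levels,
            matrix=matrix,
            coarsest_fov_mm=coarsest_fov_mm,
            finest_spacing_mm=finest_spacing_mm,
            feature_dims=feature_dims,
            convs_per_block=convs_per_block,
            decoder_kernel=decoder_kernel,
            learning_rate=learning_rate,
            batch_size=batch_size,
            n_patches=n_patches,
            label_bias=label_bias,
            topk_fraction=topk_fraction,
            validation=validation,
            n_candidates=n_candidates,
            n_keep=n_keep,
            n_passes=n_passes,
            threshold=threshold,
            inference_mode=inference_mode,
            overlap_stride_mm=overlap_stride_mm,
            random_state=random_state,
        )
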