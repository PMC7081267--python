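"""scikit-learn-style estimator tying the pipeline together.

``PocketSegmenter`` is the one-stop interface: ``fit`` voxelizes protein /
reference-pocket pairs and optimizes the U-Net on the regularized Dice
objective; ``predict`` returns ranked pocket segments per structure;
``predict_density`` exposes the raw probability field.  It follows the
scikit-learn estimator contract (``get_params`` / ``set_params``, fitted
attributes with a trailing underscore) and so composes with sklearn
tooling such as ``clone``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .grid import GridSpec
from .inference import (
    DEFAULT_MIN_VOXELS,
    DEFAULT_RESIDUE_CUTOFF,
    DEFAULT_THRESHOLD,
    Density,
    PocketSegment,
    extract_pockets,
    predict_density,
)
from .network import ArchitectureSpec, LossSpec, build_model
from .nn import UNet3D, dice_loss
from .structures import MolecularStructure, read_structure
from .training import GridDataset, TrainingConfig, train, voxelize_pair


def _as_structure(x) -> MolecularStructure:
    if isinstance(x, MolecularStructure):
        return x
    return read_structure(x)


def _as_pocket_list(y) -> list[MolecularStructure]:
    if isinstance(y, MolecularStructure) or isinstance(y, (str, Path)):
        y = [y]
    return [_as_structure(p) for p in y]


class PocketSegmenter(BaseEstimator):
    """Binding-pocket detector: 3D U-Net semantic segmentation on voxel grids.

    Parameters
    ----------
    spacing, points_per_axis:
        Lattice geometry (default 2 Å, 36 nodes → 70 Å node-to-node span).
    encoder_filters, bottleneck_filters, pool_schedule, upsample_schedule:
        Architecture; the decoder mirrors the encoder filter counts.
    epsilon, l2_lambda:
        Dice smoothing and L2 weight-penalty coefficients.
    learning_rate, steps, batch_size, augment, max_translation:
        Optimization settings (Adam).  The full-scale reference settings
        are 1.5e6 steps at 1e-6; defaults here are desk-scale.
    threshold, min_voxels, residue_cutoff:
        Post-processing: binarization threshold, minimum segment size in
        voxels, and the residue contact cutoff in Å.
    random_state:
        Seeds weight initialization and batch sampling.
    """

    def __init__(
        self,
        spacing: float = 2.0,
        points_per_axis: int = 36,
        encoder_filters: tuple[int, ...] = (32, 64, 128, 256),
        bottleneck_filters: int = 512,
        pool_schedule: tuple[int, ...] = (2, 2, 3, 3),
        upsample_schedule: tuple[int, ...] = (3, 3, 2, 2),
        epsilon: float = 0.01,
        l2_lambda: float = 1e-5,
        learning_rate: float = 1e-6,
        steps: int = 2000,
        batch_size: int = 10,
        augment: bool = True,
        max_translation: int = 3,
        threshold: float = DEFAULT_THRESHOLD,
        min_voxels: int = DEFAULT_MIN_VOXELS,
        residue_cutoff: float = DEFAULT_RESIDUE_CUTOFF,
        random_state: int = 0,
    ):
        self.spacing = spacing
        self.points_per_axis = points_per_axis
        self.encoder_filters = encoder_filters
        self.bottleneck_filters = bottleneck_filters
        self.pool_schedule = pool_schedule
        self.upsample_schedule = upsample_schedule
        self.epsilon = epsilon
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.steps = steps
        self.batch_size = batch_size
        self.augment = augment
        self.max_translation = max_translation
        self.threshold = threshold
        self.min_voxels = min_voxels
        self.residue_cutoff = residue_cutoff
        self.random_state = random_state

    # -- configuration helpers --------------------------------------------

    def _grid_template(self) -> GridSpec:
        return GridSpec(spacing=self.spacing, points_per_axis=self.points_per_axis)

    def _arch(self) -> ArchitectureSpec:
        return ArchitectureSpec(
            encoder_filters=tuple(self.encoder_filters),
            bottleneck_filters=self.bottleneck_filters,
            decoder_filters=tuple(reversed(self.encoder_filters)),
            pool_schedule=tuple(self.pool_schedule),
            upsample_schedule=tuple(self.upsample_schedule),
        )

    def _loss_spec(self) -> LossSpec:
        return LossSpec(epsilon=self.epsilon, l2_lambda=self.l2_lambda)

    def _build(self) -> UNet3D:
        model = build_model(self._arch(), seed=self.random_state)
        model.check_input_size(self.points_per_axis)
        return model

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        """Train on protein structures ``X`` and reference pockets ``y``.

        ``X``: sequence of structures (or paths); ``y``: per structure, one
        pocket point cloud or a list of them.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        template = self._grid_template()
        pairs, names = [], []
        for i, (xs, ys) in enumerate(zip(X, y)):
            protein = _as_structure(xs)
            pockets = _as_pocket_list(ys)
            pairs.append(voxelize_pair(protein, pockets, template))
            names.append(getattr(protein, "source_path", "") or f"structure_{i}")
        dataset = GridDataset(pairs, names)
        self.model_ = self._build()
        config = TrainingConfig(
            batch_size=self.batch_size,
            steps=self.steps,
            learning_rate=self.learning_rate,
            augment=self.augment,
            max_translation=self.max_translation,
            seed=self.random_state,
        )
        self.loss_trace_ = train(self.model_, dataset, config, self._loss_spec())
        self.n_structures_ = len(dataset)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise AttributeError("PocketSegmenter is not fitted; call fit() or load()")

    def predict_density(self, X) -> list[Density]:
        """Per-voxel pocket probability field for each structure."""
        self._check_fitted()
        template = self._grid_template()
        return [predict_density(self.model_, _as_structure(x), template) for x in X]

    def predict(self, X) -> list[list[PocketSegment]]:
        """Ranked pocket segments (best first) for each structure."""
        return [
            extract_pockets(d, self.threshold, self.min_voxels) for d in self.predict_density(X)
        ]

    def score(self, X, y) -> float:
        """Mean Dice coefficient (−dice loss, higher is better) over X."""
        self._check_fitted()
        template = self._grid_template()
        scores = []
        for xs, ys in zip(X, y):
            _, mask = voxelize_pair(_as_structure(xs), _as_pocket_list(ys), template)
            density = self.predict_density([xs])[0]
            scores.append(-dice_loss(density.values, mask.values, self.epsilon))
        return float(np.mean(scores))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        self.model_.save(path)

    def load(self, path: str | Path) -> "PocketSegmenter":
        """Attach weights from a checkpoint, marking the estimator fitted."""
        self.model_ = UNet3D.load(path)
        return self
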