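"""Histogram-of-oriented-gradients baseline arm.

Dense HOG descriptors are computed from the *full* image (no mask, no ROI)
and pushed through the identical Spearman-graph + GNN path, to quantify
what the handcrafted ROI features buy over an off-the-shelf whole-image
shape descriptor.

Default geometry: 224x224 input, 16x16-pixel cells, 2x2-cell blocks with a
one-cell stride and 9 unsigned orientation bins, L2-Hys block
normalization — which yields a 13*13*4*9 = 6084-long descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import hog as _sk_hog
from skimage.transform import resize as _sk_resize


class HogConfigError(ValueError):
    pass


@dataclass(frozen=True)
class HogConfig:
    image_size: int = 224
    cell_size: int = 16
    block_cells: int = 2
    orientations: int = 9

    def __post_init__(self):
        if self.image_size % self.cell_size != 0:
            raise HogConfigError("image_size must be divisible by cell_size")
        if self.block_cells > self.image_size // self.cell_size:
            raise HogConfigError("block does not fit within the cell grid")
        if min(self.orientations, self.cell_size, self.block_cells) < 1:
            raise HogConfigError("geometry parameters must be positive")

    @property
    def cells_per_side(self) -> int:
        return self.image_size // self.cell_size

    @property
    def descriptor_length(self) -> int:
        blocks = self.cells_per_side - self.block_cells + 1
        return blocks * blocks * self.block_cells**2 * self.orientations


def hog_features(image, config: HogConfig = HogConfig()) -> np.ndarray:
    """HOG descriptor of one grayscale image, resized to the config size."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if img.shape != (config.image_size, config.image_size):
        img = _sk_resize(img, (config.image_size, config.image_size),
                         anti_aliasing=True, preserve_range=True)
    vec = _sk_hog(img, orientations=config.orientations,
                  pixels_per_cell=(config.cell_size, config.cell_size),
                  cells_per_block=(config.block_cells, config.block_cells),
                  block_norm="L2-Hys", feature_vector=True)
    assert vec.size == config.descriptor_length
    return vec


def build_hog_table(cohort, config: HogConfig = HogConfig()) -> pd.DataFrame:
    """Descriptor table: one row per image (id, hog_0..hog_{L-1}, label)."""
    rows = [hog_features(image, config) for image, _mask, _label in cohort]
    X = np.vstack(rows)
    df = pd.DataFrame(X, columns=[f"hog_{i}" for i in range(X.shape[1])])
    df.insert(0, "id", np.arange(len(cohort)))
    df["label"] = [int(label) for _i, _m, label in cohort]
    return df


def hog_graph_pipeline(cohort, config: HogConfig = HogConfig(),
                       model_config=None, tau: float | None = None,
                       split=None):
    """HOG descriptors -> Spearman graph -> GNN; returns (EvalReport, Graph).

    No correlation threshold by default.  Reuses ``split`` when given so the
    comparison with the handcrafted-feature arm shares splits and seed.
    """
    from .graph import build_graph
    from .nn.model import ModelConfig, train

    table = build_hog_table(cohort, config)
    g = build_graph(table, tau=tau)
    res = train(g, model_config or ModelConfig(), split=split)
    return res.report, g


def compare_with_handcrafted(cohort, model_config=None,
                             tau_handcrafted: float | None = None,
                             hog_config: HogConfig = HogConfig()) -> dict:
    """Side-by-side accuracy of the handcrafted-feature and HOG arms.

    Both arms share the node split and seed; the handcrafted arm may use a
    correlation threshold, the HOG arm never does (its comparison condition).
    """
    from .features import build_feature_table
    from .graph import build_graph
    from .nn.model import ModelConfig, stratified_split, train

    cfg = model_config or ModelConfig()
    # keep cohort order so node ids line up across both arms
    table = build_feature_table(cohort, malignant_first=False)
    g_hand = build_graph(table, tau=tau_handcrafted)
    split = stratified_split(g_hand.labels, seed=cfg.seed)
    res_hand = train(g_hand, cfg, split=split)
    hog_report, _ = hog_graph_pipeline(
        cohort, config=hog_config, model_config=cfg, tau=None, split=split)
    return {
        "handcrafted": res_hand.report.to_dict(),
        "hog": hog_report.to_dict(),
        "accuracy_difference": res_hand.report.accuracy - hog_report.accuracy,
    }
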