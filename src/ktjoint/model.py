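"""Model/results interface to the joint reconstruction.

`KTJointModel` wraps a masked multi-coil k-t dataset and a sampling plan the
way a statistical model wraps data: construction declares what is to be
estimated and under which settings, ``fit()`` runs the two-stage estimator,
and the returned :class:`KTJointResults` carries the image-series estimate
together with its diagnostics (per-frame/coil scaling factors, kernel
calibration residual, solver objective traces) and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from .config import ReconConfig
from .core import ImageSeries, KTDataset
from .metrics import nmse as _nmse
from .metrics import temporal_profile
from .pipeline import reference_images, run_reconstruction
from .sampling import SamplingPlan

__all__ = ["KTJointModel", "KTJointResults"]


class KTJointModel:
    """Two-stage CS + nonlinear-parallel-imaging reconstruction model.

    Parameters
    ----------
    data : KTDataset or ndarray
        Masked multi-coil k-t data ``[coil, frame, ky, kx]``.
    plan : SamplingPlan
        The sampling scheme that produced the data.
    method : {"proposed", "cs_only", "zero_filled"}
    config : ReconConfig, optional
        Solver and kernel settings; ``method`` overrides the config's.
    """

    def __init__(
        self,
        data: KTDataset | np.ndarray,
        plan: SamplingPlan,
        method: str = "proposed",
        config: ReconConfig | None = None,
    ):
        if not isinstance(data, KTDataset):
            data = KTDataset(kspace=np.asarray(data))
        cfg = config or ReconConfig()
        if cfg.method != method:
            cfg = ReconConfig(
                focuss=cfg.focuss, nlgrappa=cfg.nlgrappa, metrics=cfg.metrics,
                method=method, log_level=cfg.log_level,
            )
        self.data = data
        self.plan = plan
        self.config = cfg

    @classmethod
    def from_hdf5(cls, path, method: str = "proposed", config=None) -> "KTJointModel":
        from .core import load_dataset

        data, plan = load_dataset(path)
        if plan is None:
            raise ValueError(f"{path} carries no sampling plan")
        return cls(data, plan, method=method, config=config)

    def fit(self) -> "KTJointResults":
        series, diagnostics = run_reconstruction(
            self.data, self.plan, self.config, return_diagnostics=True
        )
        return KTJointResults(self, series, diagnostics)


class KTJointResults:
    """Fitted reconstruction: image estimate plus diagnostics."""

    def __init__(self, model: KTJointModel, images: ImageSeries, diagnostics: dict):
        self.model = model
        self.images = images
        self.diagnostics = diagnostics
        self.kspace_full = diagnostics.get("kspace_full")
        self.beta_table = diagnostics.get("beta_table")
        self.kernel = diagnostics.get("kernel")

    @property
    def method(self) -> str:
        return self.model.config.method

    def nmse(self, reference=None, roi: np.ndarray | None = None) -> np.ndarray:
        """Per-frame NMSE vs a reference ImageSeries (defaults to the
        dataset's fully sampled reference)."""
        if reference is None:
            reference = reference_images(self.model.data)
        return _nmse(reference, self.images, roi=roi)

    def temporal_profile(self, x_column: int) -> np.ndarray:
        return temporal_profile(self.images, x_column)

    def summary(self) -> str:
        plan = self.model.plan
        lines = [
            "k-t joint reconstruction results",
            "=" * 40,
            f"method:            {self.method}",
            f"data:              {self.model.data.n_coils} coils, "
            f"{plan.n_frames} frames, {plan.n_pe} x {plan.n_fe}",
            f"sampling:          r1={plan.r1}, r2={plan.r2:g}, "
            f"n_acs={plan.n_acs}, sigma={plan.density_sigma:g}",
            f"net reduction R:   {plan.net_r:.3f}",
            f"acquired lines/fr: {plan.lines_per_frame().mean():.1f} of {plan.n_pe}",
            f"runtime:           {self.diagnostics.get('runtime_s', float('nan')):.2f} s",
        ]
        if self.beta_table is not None:
            bt = self.beta_table
            lines.append(
                f"scaling beta:      |beta| in [{bt.abs_beta.min():.4f}, "
                f"{bt.abs_beta.max():.4f}], median residual "
                f"{bt.residual_rel.median():.3e}"
            )
        if self.kernel is not None:
            lines.append(
                f"kernel:            {self.kernel.geometry.n_features} features, "
                f"calib residual {self.kernel.calib_residual_rel:.3e}"
            )
        try:
            vals = self.nmse()
            lines.append(
                f"NMSE vs reference: mean {vals.mean():.4e} "
                f"(min {vals.min():.4e}, max {vals.max():.4e})"
            )
        except ValueError:
            pass
        return "\n".join(lines)

    def plot_frame(self, frame: int = 0, ax=None):
        """Show one magnitude frame (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.images.magnitude[frame], cmap="gray")
        ax.set_title(f"{self.method}, frame {frame}")
        ax.axis("off")
        return ax
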