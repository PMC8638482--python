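"""Core containers and Fourier-transform conventions.

All transforms are unitary (``norm="ortho"``) and *centered*: arrays are
stored with the DC component at index ``n // 2`` in every transformed axis,
and the fftshift bookkeeping is handled internally by the helpers here.

Array layout conventions used throughout the package:

* multi-coil k-t data: complex ``[coil, frame, ky, kx]`` with ``ky`` the
  phase-encode (PE) axis and ``kx`` the frequency-encode (readout) axis;
* sampling masks: boolean ``[frame, ky]``;
* image series: ``[frame, y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "KTDataset",
    "ImageSeries",
    "cfft",
    "cifft",
    "fft2c",
    "ifft2c",
    "kt_to_xf",
    "xf_to_kt",
    "load_dataset",
    "save_dataset",
]

CONTAINER_VERSION = "1.0"


def cfft(a: np.ndarray, axis: int) -> np.ndarray:
    """Centered unitary forward DFT along one axis."""
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(a, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def cifft(a: np.ndarray, axis: int) -> np.ndarray:
    """Centered unitary inverse DFT along one axis."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(a, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def fft2c(img: np.ndarray) -> np.ndarray:
    """Image -> k-space over the last two axes (centered, unitary)."""
    return cfft(cfft(img, axis=-2), axis=-1)


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """k-space -> image over the last two axes (centered, unitary)."""
    return cifft(cifft(ksp, axis=-2), axis=-1)


def kt_to_xf(kt: np.ndarray, t_axis: int = 0, ky_axis: int = 1) -> np.ndarray:
    """Map k-t data to the x-f (space x temporal-frequency) domain.

    The spatial-frequency axis ``ky`` is inverse-transformed to ``y`` and the
    time axis is forward-transformed to temporal frequency ``f``.  This is the
    adjoint (= inverse, both unitary) of :func:`xf_to_kt`.
    """
    return cfft(cifft(kt, axis=ky_axis), axis=t_axis)


def xf_to_kt(xf: np.ndarray, f_axis: int = 0, y_axis: int = 1) -> np.ndarray:
    """Map an x-f image to k-t space (the encoding operator F)."""
    return cfft(cifft(xf, axis=f_axis), axis=y_axis)


@dataclass
class KTDataset:
    """Multi-coil dynamic Cartesian k-space data.

    Parameters
    ----------
    kspace : ndarray
        Complex array ``[coil, frame, ky, kx]``.  For an undersampled
        acquisition, unacquired entries are exactly zero.
    reference : ndarray, optional
        Fully sampled k-space of the same shape, when available (synthetic
        data, or retrospective undersampling of a full acquisition).
    meta : dict
        Free-form geometry / provenance metadata.
    """

    kspace: np.ndarray
    reference: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kspace = np.asarray(self.kspace)
        if self.kspace.ndim != 4:
            raise ValueError(
                f"kspace must be [coil, frame, ky, kx]; got ndim={self.kspace.ndim}"
            )
        if self.reference is not None and self.reference.shape != self.kspace.shape:
            raise ValueError("reference shape must match kspace shape")

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_frames(self) -> int:
        return self.kspace.shape[1]

    @property
    def n_pe(self) -> int:
        return self.kspace.shape[2]

    @property
    def n_fe(self) -> int:
        return self.kspace.shape[3]


@dataclass
class ImageSeries:
    """A coil-combined magnitude image series ``[frame, y, x]``."""

    magnitude: np.ndarray
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude)
        if self.magnitude.ndim != 3:
            raise ValueError("magnitude must be [frame, y, x]")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 with frame as the 4th dimension."""
        import nibabel as nib

        # NIfTI stores x fastest; move [frame, y, x] -> [x, y, 1, frame]
        vol = np.transpose(self.magnitude, (2, 1, 0))[:, :, None, :]
        nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), str(path))


def save_dataset(path, data: KTDataset, plan=None) -> None:
    """Write the single-file HDF5 container.

    Layout: ``/kspace`` complex64 ``[coil, frame, ky, kx]``, optional
    ``/reference``, optional sampling-plan datasets (see
    :func:`ktjoint.sampling.save_plan_group`).
    """
    from .sampling import save_plan_group

    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data.kspace.astype(np.complex64))
        if data.reference is not None:
            f.create_dataset("reference", data=data.reference.astype(np.complex64))
        f.attrs["version"] = CONTAINER_VERSION
        for k, v in data.meta.items():
            if isinstance(v, (int, float, str)):
                f.attrs[k] = v
        if plan is not None:
            save_plan_group(f, plan)


def load_dataset(path):
    """Read the HDF5 container; returns ``(KTDataset, SamplingPlan | None)``."""
    from .sampling import load_plan_group

    with h5py.File(path, "r") as f:
        ksp = f["kspace"][()]
        ref = f["reference"][()] if "reference" in f else None
        meta = {k: v for k, v in f.attrs.items()}
        plan = load_plan_group(f) if "uniform_mask" in f else None
    return KTDataset(kspace=ksp, reference=ref, meta=meta), plan
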