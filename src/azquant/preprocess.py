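"""Stack conditioning: Gaussian filtering, drift correction, baseline removal.

The default order (filter -> drift-correct -> baseline-subtract) mirrors the
standard quantal-imaging workflow: fine Gaussian filtering to reduce noise, a
rigid translational movement correction, then subtraction of a composite of
quiet frames (intervals without synaptic release) to isolate flash dF.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from azquant.containers import MovieStack


def gaussian_filter_stack(
    stack: MovieStack, sigma_px: float = 1.0, inplace: bool = False
) -> MovieStack:
    """Convolve every frame with an isotropic Gaussian (reflective edges).

    ``sigma_px = 0`` returns the input unchanged.  Total frame intensity is
    conserved away from the edges.  ``inplace`` reuses the input buffer
    (long stacks are large; the full pipeline runs in place by default).
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if sigma_px == 0:
        return stack
    out = stack.data if inplace else np.empty_like(stack.data)
    for i in range(stack.n_frames):
        ndimage.gaussian_filter(stack.data[i], sigma_px, output=out[i], mode="reflect")
    return stack.copy_with(out, gaussian_sigma_px=sigma_px)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def correct_drift(
    stack: MovieStack,
    reference: int = 0,
    upsample: int = 10,
    apply_min_px: float = 0.05,
    inplace: bool = False,
    estimation_bin: int = 1,
) -> tuple[MovieStack, pd.DataFrame]:
    """Rigid translational registration against a reference frame.

    Per-frame translation is estimated by phase cross-correlation with
    subpixel refinement at factor ``upsample``; frames are re-aligned with
    linear interpolation (reflective edges).  Shifts smaller than
    ``apply_min_px`` in both axes are left untouched.  Frames whose
    correlation peak is ambiguous -- flat frames, or candidate shifts that do
    not actually improve agreement with the reference (spurious peaks from
    featureless or flash-dominated frames) -- are flagged in the shift table
    and left in place rather than shifted on a guess.  ``estimation_bin > 1``
    estimates shifts on block-binned frames (upsampling scaled to keep the
    nominal precision), cutting the FFT cost ~bin^2-fold on long recordings;
    shifts are always applied at full resolution.

    Returns the aligned stack and a table ``(frame, dy_px, dx_px, ambiguous)``.
    """
    if stack.n_frames < 2:
        raise ValueError("need >= 2 frames to register")
    if not 0 <= reference < stack.n_frames:
        raise ValueError("reference frame out of range")
    b = int(estimation_bin)

    def _binned(img):
        if b == 1:
            return img
        h, w = (img.shape[0] // b) * b, (img.shape[1] // b) * b
        return img[:h, :w].reshape(h // b, b, w // b, b).mean(axis=(1, 3))

    ref = stack.data[reference] if inplace else stack.data[reference].copy()
    ref_b = _binned(np.asarray(ref, dtype=np.float32))
    out = stack.data if inplace else stack.data.copy()
    rows = []
    for i in range(stack.n_frames):
        if i == reference:
            rows.append((i, 0.0, 0.0, False))
            continue
        frame = stack.data[i]
        ambiguous = False
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            # flat frame: correlation surface is constant
            rows.append((i, 0.0, 0.0, True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shift, error, _ = phase_cross_correlation(
                ref_b, _binned(np.asarray(frame, dtype=np.float32)),
                upsample_factor=upsample * b, normalization=None,
            )
        dy, dx = float(shift[0]) * b, float(shift[1]) * b
        if max(abs(dy), abs(dx)) >= apply_min_px:
            # verify before committing: a genuine drift estimate must improve
            # agreement with the reference; otherwise the correlation peak was
            # spurious (featureless or flash-dominated frame) -> ambiguous
            frame_b = _binned(np.asarray(frame, dtype=np.float32))
            moved_b = ndimage.shift(frame_b, (dy / b, dx / b), order=1, mode="reflect")
            r0 = _safe_corr(ref_b, frame_b)
            r1 = _safe_corr(ref_b, moved_b)
            if r1 < 0.35 or r1 < r0 - 0.01:
                ambiguous = True
                dy = dx = 0.0
            else:
                src = frame.copy() if out[i] is frame or inplace else frame
                ndimage.shift(src, (dy, dx), output=out[i], order=1, mode="reflect")
        rows.append((i, dy, dx, ambiguous))
    shifts = pd.DataFrame(rows, columns=["frame", "dy_px", "dx_px", "ambiguous"])
    aligned = stack.copy_with(out, drift_reference=reference, drift_upsample=upsample)
    return aligned, shifts


def subtract_baseline(
    stack: MovieStack,
    quiet_frames: "str | list[int]" = "auto",
    k_frames: int = 5,
    inplace: bool = False,
) -> MovieStack:
    """Subtract a composite of quiet (release-free) frames from every frame.

    With ``quiet_frames="auto"``, quiet frames are chosen by per-frame summed
    intensity: among frames whose sum is at or above the median-frame floor
    (guarding against dropped/dark frames), the ``k_frames`` frames with the
    lowest sums are taken.  Output may be negative; the frames used are
    recorded in ``meta["baseline_frames"]``.
    """
    if k_frames < 1:
        raise ValueError("k_frames must be >= 1")
    if isinstance(quiet_frames, str):
        if quiet_frames != "auto":
            raise ValueError("quiet_frames must be 'auto' or a list of frame indices")
        sums = stack.data.reshape(stack.n_frames, -1).sum(axis=1, dtype=np.float64)
        floor = np.median(sums)
        candidates = np.nonzero(sums >= floor)[0]
        if candidates.size < k_frames:
            raise ValueError(
                f"only {candidates.size} quiet-frame candidates at the median floor; "
                f"need {k_frames}"
            )
        order = candidates[np.argsort(sums[candidates], kind="stable")]
        frames = np.sort(order[:k_frames])
    else:
        frames = np.asarray(list(quiet_frames), dtype=int)
        if frames.size < 1:
            raise ValueError("need at least one quiet frame")
        if frames.min() < 0 or frames.max() >= stack.n_frames:
            raise ValueError("quiet frame index out of range")
    composite = stack.data[frames].mean(axis=0, dtype=np.float64).astype(stack.data.dtype)
    if inplace:
        out = stack.data
        out -= composite[None]
    else:
        out = stack.data - composite[None]
    return stack.copy_with(out, baseline_frames=frames.tolist())


def default_pipeline(
    stack: MovieStack,
    sigma_px: float = 1.0,
    register: bool = True,
    quiet_frames: "str | list[int]" = "auto",
    k_frames: int = 5,
    inplace: bool = False,
    registration_bin: int = 1,
) -> tuple[MovieStack, pd.DataFrame | None]:
    """Filter -> drift-correct -> baseline-subtract, in the standard order.

    With ``inplace`` the input stack's buffer is consumed (recommended for
    long recordings; the conditioned stack replaces the raw data).
    """
    out = gaussian_filter_stack(stack, sigma_px, inplace=inplace)
    if out.data is stack.data and not inplace:
        out = stack.copy_with(stack.data.copy())
    shifts = None
    if register and stack.n_frames >= 2:
        out, shifts = correct_drift(out, inplace=True,  # buffer is already ours
                                    estimation_bin=registration_bin)
    out = subtract_baseline(out, quiet_frames=quiet_frames, k_frames=k_frames,
                            inplace=True)
    return out, shifts
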