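"""Input pipeline for the ecological (natural-image) hypercolumn model.

Grayscale images are cut into small square patches, reduced and whitened by
PCA, and fed to the network through a bank of Gabor filters sharing one
retinal location and spatial frequency but spanning all orientations.  The
composed feedforward matrix is ``W = filters @ reconstruction``: the filter
bank applied to the patch reconstructed from its whitened code.

Because the package ships no photographs, :func:`synth_textures` generates
random-phase textures with a power-law (by default 1/f^2) spatial power
spectrum and low RMS contrast — the two first-order statistics of natural
scenes that matter here: scale-free spatial correlations and the dominance
of low contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from PIL import Image

from .network import NetworkParams, LOGISTIC

#: ITU-R 601 luma weights, the standard grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# synthetic textures
# ---------------------------------------------------------------------------

def synth_textures(n: int, side: int = 256, spectrum_exponent: float = 2.0,
                   contrast_scale: float = 0.05, seed=None) -> np.ndarray:
    """Random-phase power-law textures as a stand-in for photographs.

    Returns an (n, side, side) uint8 array.  Each texture is a Gaussian
    random field whose radially averaged power spectrum falls off as
    f**(-spectrum_exponent) (1/f^2 by default, the natural-image slope),
    normalized to unit RMS and mapped to bytes around mid-gray:
    ``128 + 255 * contrast_scale * field``.  ``contrast_scale`` is the RMS
    contrast on a 0..1 luminance scale; the low default emulates the
    predominance of low contrasts in natural scenes.
    """
    if side < 64:
        raise ValueError("side must be >= 64")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.rfftfreq(side)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-spectrum_exponent / 2.0)
    out = np.empty((n, side, side), dtype=np.uint8)
    for i in range(n):
        phases = rng.standard_normal(f.shape) + 1j * rng.standard_normal(f.shape)
        field = np.fft.irfft2(amp * phases, s=(side, side))
        field /= np.sqrt(np.mean(field ** 2))
        img = 128.0 + 255.0 * contrast_scale * field
        out[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return out


def save_images(images: np.ndarray, directory, prefix: str = "texture") -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = directory / f"{prefix}_{i:04d}.png"
        Image.fromarray(img, mode="L").save(p)
        paths.append(p)
    return paths


def load_image(path) -> np.ndarray:
    """Load an image file as a 2-D uint8 grayscale array."""
    img = Image.open(path)
    if img.mode != "L":
        img = img.convert("L")  # PIL uses the ITU-R 601 luma transform
    return np.asarray(img, dtype=np.uint8)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Flattened grayscale patches, byte scale 0-255 (centered later)."""

    patches: np.ndarray     # (n, p*p) float
    patch_side: int


def _as_gray_array(image, name):
    if isinstance(image, (str, Path)):
        return load_image(image), str(image)
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr @ _LUMA
    return arr.astype(float), name


def extract_patches(images, patch_side: int = 25, n: int = 10_000,
                    seed=None) -> PatchSet:
    """Cut ``n`` patches at uniform-random locations from the given images.

    ``images`` is a sequence of 2-D arrays, RGB arrays (converted with the
    standard luminance weights) or file paths.  Locations are seeded and
    reproducible; an image smaller than ``patch_side`` raises an error
    naming it.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    arrays = []
    for idx, image in enumerate(images):
        arr, name = _as_gray_array(image, f"image #{idx}")
        if arr.shape[0] < patch_side or arr.shape[1] < patch_side:
            raise ValueError(
                f"{name} ({arr.shape[0]}x{arr.shape[1]}) is smaller than "
                f"the patch side {patch_side}")
        arrays.append(arr)
    n_img = len(arrays)
    if n_img == 0:
        raise ValueError("no images given")
    out = np.empty((n, patch_side * patch_side))
    which = rng.integers(0, n_img, size=n)
    for k in range(n):
        arr = arrays[which[k]]
        r = rng.integers(0, arr.shape[0] - patch_side + 1)
        c = rng.integers(0, arr.shape[1] - patch_side + 1)
        out[k] = arr[r:r + patch_side, c:c + patch_side].ravel()
    return PatchSet(patches=out, patch_side=patch_side)


# ---------------------------------------------------------------------------
# PCA + whitening
# ---------------------------------------------------------------------------

@dataclass
class WhiteningModel:
    """PCA reduction to d components with variance whitening.

    Patches are rescaled from bytes to a 0..1 luminance scale and mean-
    centered; the code of a patch is ``diag(1/sqrt(lambda)) V^T (p - mean)``
    so training codes have identity covariance.  ``reconstruction``
    (= V diag(sqrt(lambda)), shape p^2 x d) maps codes back to centered
    pixel space and is the right factor of the composed feedforward matrix.
    """

    mean_vector: np.ndarray    # (p*p,) in 0..1 units
    eigenvectors: np.ndarray   # (p*p, d), columns, descending eigenvalue
    eigenvalues: np.ndarray    # (d,) regularized, descending
    patch_side: int

    @property
    def d(self) -> int:
        return self.eigenvalues.size

    @property
    def reconstruction(self) -> np.ndarray:
        return self.eigenvectors * np.sqrt(self.eigenvalues)

    def transform(self, patches: np.ndarray, byte_scale: bool = True,
                  center: bool = True) -> np.ndarray:
        """Whitened codes, shape (n, d).

        ``byte_scale=False`` treats the input as already on the 0..1 scale
        (e.g. a synthetic zero-mean probe pattern, with ``center=False``).
        """
        P = np.atleast_2d(np.asarray(patches, dtype=float))
        if byte_scale:
            P = P / 255.0
        if center:
            P = P - self.mean_vector
        return (P @ self.eigenvectors) / np.sqrt(self.eigenvalues)

    def reconstruct(self, codes: np.ndarray) -> np.ndarray:
        """Centered 0..1-scale patches from codes (mean not re-added)."""
        return np.atleast_2d(np.asarray(codes, float)) @ self.reconstruction.T

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "mean_vector.csv", self.mean_vector,
                   delimiter=",", fmt="%.17g")
        np.savetxt(directory / "eigenvectors.csv", self.eigenvectors,
                   delimiter=",", fmt="%.17g")
        np.savetxt(directory / "eigenvalues.csv", self.eigenvalues,
                   delimiter=",", fmt="%.17g")
        (directory / "whitening.json").write_text(
            json.dumps({"patch_side": self.patch_side, "d": int(self.d)}))

    @classmethod
    def load(cls, directory) -> "WhiteningModel":
        directory = Path(directory)
        meta = json.loads((directory / "whitening.json").read_text())
        return cls(
            mean_vector=np.loadtxt(directory / "mean_vector.csv",
                                   delimiter=","),
            eigenvectors=np.loadtxt(directory / "eigenvectors.csv",
                                    delimiter=",", ndmin=2),
            eigenvalues=np.atleast_1d(
                np.loadtxt(directory / "eigenvalues.csv", delimiter=",")),
            patch_side=int(meta["patch_side"]),
        )


def fit_whitening(patches: PatchSet, d: int = 100,
                  eig_floor_rel: float = 1e-8) -> WhiteningModel:
    """Fit the PCA + whitening model on a patch set.

    Keeps the top ``d`` principal components; each eigenvalue is floored at
    ``eig_floor_rel`` times the largest to keep the inverse square root
    bounded.
    """
    P = patches.patches / 255.0
    n = P.shape[0]
    if n <= d:
        raise ValueError(f"need more than d={d} patches, got {n}")
    mean = P.mean(axis=0)
    Pc = P - mean
    cov = (Pc.T @ Pc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:d]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.maximum(evals, eig_floor_rel * evals[0])
    return WhiteningModel(mean_vector=mean, eigenvectors=evecs,
                          eigenvalues=evals, patch_side=patches.patch_side)


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

def gabor_patch(patch_side: int, orientation: float, wavelength: float = 12.0,
                sigma: float = 7.0, phase: float = 0.0,
                normalize: bool = True) -> np.ndarray:
    """One centered Gabor pattern, flattened to (p*p,).

    ``orientation`` (radians) is the orientation of the stripes; the
    carrier runs perpendicular to them.  Mean-subtracted and unit-normed
    when ``normalize`` (the default, matching the filter bank convention).
    """
    half = (patch_side - 1) / 2.0
    coords = np.arange(patch_side) - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    across = xx * np.cos(orientation) + yy * np.sin(orientation)
    env = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    gb = env * np.cos(2.0 * np.pi * across / wavelength + phase)
    gb = gb.ravel()
    if normalize:
        gb = gb - gb.mean()
        gb = gb / np.linalg.norm(gb)
    return gb


@dataclass
class GaborBank:
    """M Gabor filters sharing center, frequency, envelope and phase."""

    filters: np.ndarray       # (M, p*p), mean-subtracted, unit-normed rows
    orientations: np.ndarray  # (M,) radians, equally spaced in [0, pi)
    patch_side: int
    wavelength: float
    sigma: float
    phase: float

    @property
    def M(self) -> int:
        return self.filters.shape[0]

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.degrees(self.orientations)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "filters.csv", self.filters, delimiter=",",
                   fmt="%.17g")
        meta = {"patch_side": self.patch_side, "wavelength": self.wavelength,
                "sigma": self.sigma, "phase": self.phase, "M": int(self.M)}
        (directory / "gabor_bank.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "GaborBank":
        directory = Path(directory)
        meta = json.loads((directory / "gabor_bank.json").read_text())
        M = int(meta["M"])
        return cls(
            filters=np.loadtxt(directory / "filters.csv", delimiter=",",
                               ndmin=2),
            orientations=np.pi * np.arange(M) / M,
            patch_side=int(meta["patch_side"]),
            wavelength=float(meta["wavelength"]),
            sigma=float(meta["sigma"]),
            phase=float(meta["phase"]),
        )


def gabor_bank(M: int, patch_side: int = 25, wavelength: float = 12.0,
               sigma: float = 7.0, phase: float = 0.0) -> GaborBank:
    """Bank of M Gabors with orientations i * 180/M degrees, i = 0..M-1."""
    if M < 2:
        raise ValueError("need at least 2 filters")
    orientations = np.pi * np.arange(M) / M
    filters = np.stack([
        gabor_patch(patch_side, ori, wavelength, sigma, phase)
        for ori in orientations
    ])
    return GaborBank(filters=filters, orientations=orientations,
                     patch_side=patch_side, wavelength=wavelength,
                     sigma=sigma, phase=phase)


def compose_feedforward(bank: GaborBank, model: WhiteningModel) -> np.ndarray:
    """W = filters @ reconstruction: the M x d feedforward matrix.

    Applying W to a whitened code gives exactly the filter responses to the
    patch reconstructed from that code.
    """
    if bank.patch_side != model.patch_side:
        raise ValueError(
            f"bank patch side {bank.patch_side} != whitening patch side "
            f"{model.patch_side}")
    return bank.filters @ model.reconstruction


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class TexturePipeline:
    """Everything needed to train the ecological model on textures."""

    params: NetworkParams      # Gabor-through-whitening W, K = 0
    model: WhiteningModel
    bank: GaborBank
    codes: np.ndarray          # (n_patches, d) whitened training codes

    @property
    def mean_code_rms(self) -> float:
        """Mean RMS of the training codes; the 'typical contrast' probe."""
        return float(np.mean(np.sqrt(np.mean(self.codes ** 2, axis=1))))

    def code_sampler(self):
        """Sampler drawing training codes with replacement (for train())."""
        codes = self.codes

        def sampler(n, rng):
            idx = rng.integers(0, codes.shape[0], size=n)
            return codes[idx]

        return sampler

    def probe_code(self, orientation_deg: float,
                   contrast: float | None = None) -> np.ndarray:
        """Whitened code of an oriented Gabor probe.

        The probe pattern has the same wavelength, envelope and phase as
        the feedforward filters; its code is rescaled so the RMS per
        component equals ``contrast`` (default: the mean RMS of the
        training codes, i.e. the typical training contrast).
        """
        if contrast is None:
            contrast = self.mean_code_rms
        patt = gabor_patch(
            self.bank.patch_side, np.radians(orientation_deg),
            self.bank.wavelength, self.bank.sigma, self.bank.phase)
        code = self.model.transform(patt, byte_scale=False, center=False)[0]
        rms = np.sqrt(np.mean(code ** 2))
        return code * (contrast / rms)


def build_texture_pipeline(
    n_textures: int = 20, side: int = 128, n_patches: int = 8000,
    patch_side: int = 25, d: int = 10, M: int = 60,
    wavelength: float = 12.0, sigma: float = 7.0, phase: float = 0.0,
    spectrum_exponent: float = 2.0, contrast_scale: float = 0.05,
    seed: int = 0,
) -> TexturePipeline:
    """Synthetic textures -> patches -> whitening -> Gabor feedforward net."""
    rng = np.random.default_rng(seed)
    textures = synth_textures(n_textures, side, spectrum_exponent,
                              contrast_scale, rng)
    patches = extract_patches(textures, patch_side, n_patches, rng)
    model = fit_whitening(patches, d=d)
    bank = gabor_bank(M, patch_side, wavelength, sigma, phase)
    W = compose_feedforward(bank, model)
    params = NetworkParams(W=W, K=np.zeros((M, M)), tau=1.0,
                           nonlinearity=LOGISTIC)
    codes = model.transform(patches.patches)
    return TexturePipeline(params=params, model=model, bank=bank, codes=codes)
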