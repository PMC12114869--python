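"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, each a pure function of (scenario, seed):

* :func:`generate_image` — copy-stand-style inflorescence photographs on a
  dark background: a textured bud ellipse, stigma filaments drawn without
  anti-aliasing (so the ground-truth mask is exact) whose pixels are colored
  at the yellow anchor with probability ``amber_fraction`` and at white
  otherwise, and near-white trichome speckle as a deliberate confounder.
* :func:`generate_cohort` — 4-stage cannabinoid trajectories for a
  genotype panel with a planted chemovar mix and per-genotype peak stages,
  with total concentrations inside a configured mg/g range.
* :func:`generate_spectra` — linear-mixture (Beer-Lambert) NIR spectra on a
  128-channel 950-1650 nm grid: polynomial baseline plus per-analyte Gaussian
  bands scaled by concentration, with multiplicative scatter and additive
  noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line
from skimage.morphology import disk as _disk_footprint

from . import amber
from . import color as ce
from ._bands import BAND_LIBRARY
from .cannabinoids import ANALYTES, STAGES, CannabinoidProfile, InflorescenceRecord
from .chemometrics import SpectraMatrix

# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


@dataclass
class ImageScenario:
    """Controls for one synthetic inflorescence photograph.

    The default geometry keeps structures proportional to the copy-stand
    setup the segmentation constants were designed for: on a 512 px canvas
    the bud spans ~320 px, stigma filaments are ~7 px wide (wide enough to
    survive an 11 px median) and trichome dots are 1-2 px specks.
    """

    canvas: tuple[int, int] = (512, 512)
    bud_axes: tuple[float, float] = (160.0, 125.0)  # semi-axes, px
    bud_color: tuple[int, int, int] = (60, 110, 50)
    bud_texture: float = 0.25  # multiplicative texture amplitude
    n_stigmas: int = 40
    filament_length: float = 40.0
    filament_width: int = 7
    amber_fraction: float = 0.0
    jitter_sigma: float = 5.0  # per-pixel RGB channel jitter, counts
    trichome_count: int = 250
    background_level: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amber_fraction <= 1.0:
            raise ValueError(f"amber_fraction must be in [0, 1], got {self.amber_fraction}")


_YELLOW = np.array([255, 255, 0], dtype=float)
_WHITE = np.array([255, 255, 255], dtype=float)


def generate_image(s: ImageScenario) -> tuple[np.ndarray, np.ndarray, float]:
    """Render one scene; returns (rgb, truth_stigma_mask, truth_mean_yellowness).

    The truth yellowness is the amber-score index evaluated on the drawn
    stigma pixels themselves, so generator truth and scorer are consistent by
    construction.  Filament geometry is validated against the canvas.
    """
    rng = np.random.default_rng(s.seed)
    h, w = s.canvas
    cy, cx = h / 2.0, w / 2.0
    ay, ax = s.bud_axes

    img = np.full((h, w, 3), s.background_level, dtype=float)
    img += rng.normal(0, 1.5, size=img.shape)

    # textured bud ellipse; channel ceiling keeps bud K above the stigma gate
    yy, xx = np.indices((h, w))
    inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    tex = 1.0 + s.bud_texture * (rng.random((h, w)) - 0.5) * 2.0
    for i, c in enumerate(s.bud_color):
        chan = img[..., i]
        chan[inside] = np.minimum(c * tex[inside], 144.0)

    # trichome speckle: 1-2 px neutral (white-anchor-hued) dots on the bud.
    # Tiny translucent glands image as mixed pixels, dimmer than stigma
    # filaments; when they leak into a stigma mask their near-zero b* drags
    # the amber score down (the known confusion mode).
    ty = rng.uniform(cy - ay, cy + ay, size=s.trichome_count)
    tx = rng.uniform(cx - ax, cx + ax, size=s.trichome_count)
    for y0, x0 in zip(ty, tx):
        if ((y0 - cy) / ay) ** 2 + ((x0 - cx) / ax) ** 2 > 0.92:
            continue
        rr, cc = _draw_disk((y0, x0), rng.uniform(0.7, 1.2), shape=(h, w))
        g = rng.uniform(118.0, 142.0)
        img[rr, cc] = np.clip([g, g, g * 0.97] + rng.normal(0, 3, size=3), 90, 144)

    # stigma filaments: jagged polylines radiating outward, no anti-aliasing
    mask = np.zeros((h, w), dtype=bool)
    foot = _disk_footprint(max(s.filament_width // 2, 1))
    fr = foot.shape[0] // 2
    for _ in range(s.n_stigmas):
        theta = rng.uniform(0, 2 * np.pi)
        u = rng.uniform(0.35, 0.7)
        y0 = cy + u * ay * np.sin(theta)
        x0 = cx + u * ax * np.cos(theta)
        length = s.filament_length * rng.uniform(0.7, 1.3)
        phi = theta + rng.normal(0, 0.35)
        y1 = y0 + length * np.sin(phi)
        x1 = x0 + length * np.cos(phi)
        if not (fr <= y1 < h - fr and fr <= x1 < w - fr):
            raise ValueError("stigma geometry exceeds canvas; enlarge canvas or shorten filaments")
        rr, cc = _draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        line_mask = np.zeros((h, w), dtype=bool)
        line_mask[rr, cc] = True
        # thicken by stamping the disk footprint (still aliasing-free)
        from scipy.ndimage import binary_dilation

        mask |= binary_dilation(line_mask, structure=foot)

    n_px = int(mask.sum())
    is_amber = rng.random(n_px) < s.amber_fraction
    colors = np.where(is_amber[:, None], _YELLOW, _WHITE)
    if s.jitter_sigma > 0:
        colors = colors + rng.normal(0, s.jitter_sigma, size=colors.shape)
    img[mask] = colors
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth_mask = np.where(mask, ce.FG, ce.BG).astype(np.uint8)
    if n_px:
        truth = float(amber.yellowness_index(ce.rgb_to_lab(rgb), truth_mask).mean_score)
    else:
        truth = float("nan")
    return rgb, truth_mask, truth


#: Amber fractions used to emulate the four maturity stages: chosen so the
#: expected automated score sits at the population stage-center defaults.
STAGE_AMBER_FRACTIONS = {1: 0.28, 2: 0.37, 3: 0.54, 4: 0.65}


def image_for_stage(stage: int, seed: int, **overrides) -> tuple[np.ndarray, np.ndarray, float]:
    """Convenience: a scene whose amber fraction matches a maturity stage."""
    s = ImageScenario(amber_fraction=STAGE_AMBER_FRACTIONS[stage], seed=seed, **overrides)
    return generate_image(s)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortScenario:
    """Controls for the genotype panel of 4-stage concentration trajectories."""

    n_genotypes: int = 25
    chemovar_mix: tuple[int, int, int] = (9, 5, 11)  # high-THCA, high-CBDA, even-ratio
    tcc_range: tuple[float, float] = (4.03, 87.06)  # mg/g, peak amplitudes
    #: planted TCC peak-stage counts across stages 1-4
    tcc_peak_mix: tuple[int, int, int, int] = (1, 2, 10, 12)
    weight_range: tuple[float, float] = (2.0, 60.0)  # g, genotype base weight
    decay: tuple[float, float] = (0.08, 0.20)  # relative TCC drop per stage off-peak
    noise_rel: float = 0.02  # relative trajectory noise
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.chemovar_mix) != self.n_genotypes:
            raise ValueError("chemovar mix must sum to n_genotypes")
        if sum(self.tcc_peak_mix) != self.n_genotypes:
            raise ValueError("tcc peak mix must sum to n_genotypes")


def generate_cohort(s: CohortScenario) -> tuple[list[InflorescenceRecord], pd.DataFrame]:
    """Generate 4 records per genotype plus a truth table of planted structure.

    The truth table records the generator's own argmax over the realized
    (noisy) trajectories, so downstream peak-counting can be checked exactly.
    CBGA decays after stage 1 for high-THCA and even-ratio genotypes and
    peaks at stage 3 for high-CBDA genotypes.
    """
    rng = np.random.default_rng(s.seed)
    labels = (
        ["high-THCA"] * s.chemovar_mix[0]
        + ["high-CBDA"] * s.chemovar_mix[1]
        + ["even-ratio"] * s.chemovar_mix[2]
    )
    rng.shuffle(labels)
    peak_stages = np.repeat([1, 2, 3, 4], s.tcc_peak_mix)
    rng.shuffle(peak_stages)

    records: list[InflorescenceRecord] = []
    truth_rows = []
    minors = [a for a in ANALYTES if a not in ("CBDA", "THCA", "CBGA")]
    for g in range(s.n_genotypes):
        gid = f"G{g + 1:02d}"
        label = labels[g]
        peak = int(peak_stages[g])
        amp = rng.uniform(*s.tcc_range)
        decay = rng.uniform(*s.decay)
        if label == "high-THCA":
            ratio = rng.uniform(0.05, 0.25)  # CBDA:THCA well below 1/3
        elif label == "high-CBDA":
            ratio = rng.uniform(5.0, 15.0)
        else:
            ratio = rng.uniform(0.6, 1.7)
        base_w = rng.uniform(*s.weight_range)
        minor_frac = rng.dirichlet(np.ones(len(minors))) * 0.06

        tcc_series = []
        tcy_series = []
        stage_records = []
        for stage in STAGES:
            shape = max(1.0 - decay * abs(stage - peak), 0.05)
            tcc = amp * shape * (1.0 + rng.normal(0, s.noise_rel))
            tcc = float(np.clip(tcc, 0.5, s.tcc_range[1]))
            # CBGA trajectory shape by chemovar
            if label == "high-CBDA":
                cbga_frac = 0.04 * (0.4 + 0.6 * (1.0 - abs(stage - 3) / 3.0))
            else:
                cbga_frac = 0.04 * (1.0 if stage == 1 else 0.35 / stage)
            major = tcc * (1.0 - 0.06 - cbga_frac)
            cbda = major * ratio / (1.0 + ratio)
            thca = major - cbda
            conc = {"CBDA": cbda, "THCA": thca, "CBGA": tcc * cbga_frac}
            for a, f in zip(minors, minor_frac):
                conc[a] = tcc * f
            # exact closure: nudge the largest minor so the 14-term sum == tcc
            resid = tcc - sum(conc.values())
            conc[minors[0]] = max(conc[minors[0]] + resid, 0.0)
            profile = CannabinoidProfile(conc)

            weight = base_w * (0.55 + 0.15 * stage) * (1.0 + rng.normal(0, 0.05))
            weight = float(max(weight, 0.1))
            day = 31.0 + (stage - 1) * 28.0 + rng.normal(0, 2.0)
            rec = InflorescenceRecord(
                genotype_id=gid,
                amber_stage=stage,
                harvest_day=float(day),
                inflorescence_weight=weight,
                profile=profile,
            )
            stage_records.append(rec)
            realized = sum(profile.concentrations.values())
            tcc_series.append(realized)
            tcy_series.append(realized * weight / 1000.0)

        records.extend(stage_records)
        truth_rows.append(
            {
                "genotype": gid,
                "chemovar": label,
                "planted_peak_stage": peak,
                "tcc_peak_stage": int(np.argmax(tcc_series)) + 1,
                "tcy_peak_stage": int(np.argmax(tcy_series)) + 1,
                "tcc_amplitude": amp,
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectraScenario:
    """Controls for the linear-mixture NIR spectra generator.

    The additive noise level is expressed as a signal-to-noise ratio: the RMS
    of the noiseless concentration-driven signal (deviations of the clean
    spectra from their mean) divided by the per-channel noise sd.  Setting
    ``noise_sd`` explicitly overrides the SNR-derived level; ``snr=None``
    with ``noise_sd=None`` disables additive noise.
    """

    wavelengths: np.ndarray = field(default_factory=lambda: np.linspace(950.0, 1650.0, 128))
    baseline_coefs: tuple[float, float, float] = (0.45, 0.12, -0.04)  # in scaled wavelength
    #: broad constant matrix features (center nm, width nm, amplitude), emulating
    #: the water/cellulose bands that dominate plant NIR absorbance
    matrix_bands: tuple = ((1450.0, 55.0, 0.30), (1190.0, 70.0, 0.12))
    scatter_sd: float = 0.05  # multiplicative, per spectrum
    snr: float | None = 100.0  # signal RMS / additive-noise sd
    noise_sd: float | None = None  # explicit per-channel noise sd (overrides snr)
    seed: int = 0


def _band_matrix(wavelengths: np.ndarray) -> np.ndarray:
    """14 x p matrix of unit-concentration analyte band shapes."""
    B = np.zeros((len(ANALYTES), wavelengths.shape[0]))
    for i, a in enumerate(ANALYTES):
        for center, width, amp in BAND_LIBRARY[a]:
            B[i] += amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return B


def generate_spectra(
    records: list[InflorescenceRecord], s: SpectraScenario
) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Beer-Lambert mixture spectra for a cohort, with the aligned targets.

    spectrum = baseline + sum_a conc_a * band_a, then per-spectrum
    multiplicative scatter and per-channel additive noise.  With scatter and
    noise disabled the mixture is exactly linear in concentrations.
    """
    rng = np.random.default_rng(s.seed)
    wl = np.asarray(s.wavelengths, dtype=float)
    B = _band_matrix(wl)
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    baseline = sum(c * t**k for k, c in enumerate(s.baseline_coefs))
    for center, width, amp in s.matrix_bands:
        baseline = baseline + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    conc = np.array(
        [[rec.profile[a] for a in ANALYTES] for rec in records], dtype=float
    )
    signal = conc @ B
    X = baseline[None, :] + signal
    noise_sd = s.noise_sd
    if noise_sd is None and s.snr is not None:
        noise_sd = float(np.sqrt(((signal - signal.mean(0)) ** 2).mean())) / s.snr
    if s.scatter_sd > 0:
        X = X * (1.0 + rng.normal(0, s.scatter_sd, size=(X.shape[0], 1)))
    if noise_sd:
        X = X + rng.normal(0, noise_sd, size=X.shape)

    targets = pd.DataFrame(conc, columns=list(ANALYTES))
    targets.insert(0, "sample_id", [f"{r.genotype_id}_s{r.amber_stage}" for r in records])
    targets["TCC"] = conc.sum(axis=1)
    return SpectraMatrix(values=X, wavelengths=wl), targets


def learnable_analytes(
    records: list[InflorescenceRecord], s: SpectraScenario, min_snr: float = 10.0
) -> list[str]:
    """Analytes whose concentration-driven signal clears the additive noise floor.

    An analyte counts as learnable when the RMS of its own contribution to
    the spectral deviations (band shape times centered concentration) exceeds
    ``min_snr`` times the per-channel noise sd of the scenario.  The default
    factor of 10 follows the usual quantification-limit convention (signal at
    least an order of magnitude above noise); analytes at 1-3x the noise sd
    are detectable at best, not quantifiable.  Zero-amplitude analytes are
    never learnable.
    """
    wl = np.asarray(s.wavelengths, dtype=float)
    B = _band_matrix(wl)
    conc = np.array([[rec.profile[a] for a in ANALYTES] for rec in records], dtype=float)
    signal = conc @ B
    noise_sd = s.noise_sd
    if noise_sd is None:
        if s.snr is None:
            noise_sd = 0.0
        else:
            noise_sd = float(np.sqrt(((signal - signal.mean(0)) ** 2).mean())) / s.snr
    out = []
    for i, a in enumerate(ANALYTES):
        dev = (conc[:, i] - conc[:, i].mean())[:, None] * B[i]
        if np.sqrt((dev**2).mean()) > min_snr * noise_sd:
            out.append(a)
    return out
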