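"""Synthetic glycopeptide MS/MS spectra with known fucosylation labels.

The generator encodes the diagnostic-ion pairing logic that distinguishes
the four fucosylation classes in real CID spectra:

* core fucose rides on the peptide-proximal GlcNAc, so it is retained in
  the peptide-bearing Y ions — core spectra pair Yn with YnF but show no
  fucosylated oxonium (B-series) ions;
* outer (antenna) fucose travels with the glycan-only oxonium fragments —
  outer spectra pair B ions with their +Fuc partners (B2/B2F, and
  B3S/B3SF when sialylated) but show no YnF ions;
* dual spectra show both groups; unfucosylated spectra show neither.

Each synthetic spectrum places the class-appropriate subset of the 14
diagnostic ions at its theoretical m/z (truncated Gaussian jitter) with a
log-normal intensity drawn from a per-ion law, then adds low-intensity
random noise peaks. The default intensity laws follow the abundance
structure of real CID spectra of tryptic N-glycopeptides: the small
glycosidic fragments (B2, B3S, Y1, Y2 and their fucosylated partners) are
strong and reproducible, while the larger intermediates (B3, B3F, Y3, Y4)
sit close to the detection limit and are noisier — occasionally falling
below the signal-to-noise gate, which makes their presence naturally
variable. A rule-based oracle classifier inverts the pairing logic, giving
a ground-truth contract that the learned models can be validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureVector
from .glycan import (
    B_FUC_IONS,
    DIAGNOSTIC_ION_ORDER,
    Y_FUC_IONS,
    GlycanComposition,
    GlycopeptideID,
    diagnostic_ion_set,
    feasible_ions,
    format_glycopeptide_id,
    peptide_mass,
)
from .spectra import CLASS_ORDER, GsmRecord, Peak, Spectrum

#: Tryptic glycopeptide backbones typical of plasma glycoproteins.
DEFAULT_PEPTIDE_POOL: tuple[str, ...] = (
    "VCQDCPLLAPLNDTR",
    "EEQYNSTYR",
    "NEEYNK",
    "ENGTVSR",
    "SWPAVGNCSSALR",
    "LCPDCPLLAPLNDSR",
)

#: Compositions favoured by core-dominant classes (mono/bi/hybrid) and by
#: outer-dominant classes (tri/tetra-antennary): (n_hex, n_hexnac, n_sia).
#: The generator adds the class-appropriate fucose count.
CORE_LIKE_COMPOSITIONS: tuple[tuple[int, int, int], ...] = (
    (4, 3, 0), (4, 3, 1), (5, 4, 0), (5, 4, 1), (5, 4, 2), (6, 3, 0),
)
OUTER_LIKE_COMPOSITIONS: tuple[tuple[int, int, int], ...] = (
    (6, 5, 1), (6, 5, 2), (6, 5, 3), (7, 6, 2), (7, 6, 3), (7, 6, 4),
)

#: Class proportions of a typical manually curated training set
#: (none / core / outer / dual).
DEFAULT_CLASS_MIX: tuple[float, ...] = (0.39, 0.25, 0.21, 0.15)

_STRONG_LAW = (math.log(100.0), 0.15)  # abundant ions: ~100 a.u., ~15% CV
#: Per-ion log-normal intensity laws (mu, sigma of log intensity). The
#: larger glycan intermediates are an order of magnitude weaker and more
#: variable, as in real CID spectra.
DEFAULT_INTENSITY_LAWS: Mapping[str, tuple[float, float]] = MappingProxyType(
    {
        **{ion: _STRONG_LAW for ion in DIAGNOSTIC_ION_ORDER},
        "B3": (math.log(12.0), 0.3),
        "B3F": (math.log(12.0), 0.3),
        "Y3": (math.log(25.0), 0.3),
        "Y4": (math.log(12.0), 0.3),
    }
)


@dataclass(frozen=True)
class ClassTemplate:
    """Generative recipe for one fucosylation class.

    ``present_ions`` is the maximal ion panel for the class; at generation
    time it is intersected with the ions feasible for the glycopeptide's
    composition. ``intensity_laws`` maps each ion to log-normal (mu, sigma);
    ``dropout_prob`` independently omits each present ion; noise peaks are
    uniform in m/z with log-normal intensities far below the signal regime.
    """

    label: str
    present_ions: frozenset[str]
    intensity_laws: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_LAWS)
    dropout_prob: float = 0.0
    mz_jitter_sd: float = 0.004
    n_noise_peaks: int = 30
    noise_intensity_mu: float = math.log(2.0)
    noise_intensity_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.label!r}")
        missing = self.present_ions - set(self.intensity_laws)
        if missing:
            raise ValueError(f"no intensity law for ion(s) {sorted(missing)}")
        b_fuc = self.present_ions & set(B_FUC_IONS)
        y_fuc = self.present_ions & set(Y_FUC_IONS)
        if self.label == "none" and (b_fuc or y_fuc):
            raise ValueError("'none' template must not contain fucosylated ions")
        if self.label == "core" and (b_fuc or not y_fuc):
            raise ValueError("'core' template needs YnF ions and no B-series F ions")
        if self.label == "outer" and (y_fuc or not b_fuc):
            raise ValueError("'outer' template needs B-series F ions and no YnF ions")
        if self.label == "dual" and not (b_fuc and y_fuc):
            raise ValueError("'dual' template needs both fucosylated ion groups")


_BACKBONE_IONS = frozenset(
    l for l in DIAGNOSTIC_ION_ORDER
    if l not in B_FUC_IONS and l not in Y_FUC_IONS
)


def default_templates(**overrides) -> dict[str, ClassTemplate]:
    """The four class templates implementing the diagnostic pairing logic."""
    panels = {
        "none": _BACKBONE_IONS,
        "core": _BACKBONE_IONS | set(Y_FUC_IONS),
        "outer": _BACKBONE_IONS | set(B_FUC_IONS),
        "dual": _BACKBONE_IONS | set(B_FUC_IONS) | set(Y_FUC_IONS),
    }
    return {
        label: ClassTemplate(label=label, present_ions=frozenset(panel), **overrides)
        for label, panel in panels.items()
    }


def noiseless_templates() -> dict[str, ClassTemplate]:
    """Templates with zero jitter, dropout, intensity spread and noise
    peaks: each present ion appears exactly at its theoretical m/z with a
    deterministic intensity (oracle-exact spectra)."""
    laws = {ion: (mu, 0.0) for ion, (mu, _) in DEFAULT_INTENSITY_LAWS.items()}
    return default_templates(intensity_laws=laws, dropout_prob=0.0,
                             mz_jitter_sd=0.0, n_noise_peaks=0)


def generate_gsm(
    template: ClassTemplate,
    gp: GlycopeptideID,
    seed: int,
    title: str | None = None,
    source: str = "synthetic",
) -> tuple[Spectrum, GsmRecord]:
    """One synthetic spectrum + GSM record carrying the true class label."""
    if template.label != "none" and gp.composition.n_fuc < 1:
        raise ValueError(
            f"{template.label} template requires n_fuc >= 1, "
            f"got {format_glycopeptide_id(gp)}"
        )
    if template.label == "none" and gp.composition.n_fuc > 0:
        raise ValueError(
            f"'none' template requires n_fuc = 0, got {format_glycopeptide_id(gp)}"
        )
    rng = np.random.default_rng(seed)
    theoretical = dict(diagnostic_ion_set(gp))
    ions = [l for l in feasible_ions(gp) if l in template.present_ions]

    peaks: list[Peak] = []
    for label in ions:
        if template.dropout_prob > 0 and rng.random() < template.dropout_prob:
            continue
        mu, sigma = template.intensity_laws[label]
        intensity = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else math.exp(mu)
        jitter = 0.0
        if template.mz_jitter_sd > 0:
            # truncate so the peak always stays inside the +/-0.02 Da window
            jitter = float(np.clip(rng.normal(0.0, template.mz_jitter_sd),
                                   -0.01, 0.01))
        peaks.append(Peak(theoretical[label] + jitter, intensity))

    n_placed = 0
    while n_placed < template.n_noise_peaks:
        mz = float(rng.uniform(150.0, 2500.0))
        if any(abs(mz - d) < 0.1 for d in theoretical.values()):
            continue  # keep random noise out of the diagnostic windows
        intensity = float(np.exp(rng.normal(template.noise_intensity_mu,
                                            template.noise_intensity_sigma)))
        peaks.append(Peak(mz, intensity))
        n_placed += 1

    gp_id = format_glycopeptide_id(gp)
    if title is None:
        title = f"syn.{template.label}.{gp_id}.{seed}"
    precursor_neutral = peptide_mass(gp.peptide) + gp.composition.residue_mass()
    precursor_mz = (precursor_neutral + 2 * 1.00728) / 2
    spectrum = Spectrum(title=title, precursor_mz=precursor_mz,
                        precursor_charge=2, peaks=peaks)
    gsm = GsmRecord(spectrum_title=title, glycopeptide=gp,
                    manual_label=template.label, source=source)
    return spectrum, gsm


def _composition_for(label: str, rng: np.random.Generator,
                     antennarity_bias: float) -> GlycanComposition:
    """Draw a composition; antennarity correlates with class (outer/dual
    favour tri/tetra-antennary, none/core favour mono/bi/hybrid)."""
    outer_like = label in ("outer", "dual")
    if rng.random() >= antennarity_bias:
        outer_like = not outer_like
    pool = OUTER_LIKE_COMPOSITIONS if outer_like else CORE_LIKE_COMPOSITIONS
    h, n, s = pool[rng.integers(len(pool))]
    n_fuc = {"none": 0, "core": 1, "outer": 1, "dual": 2}[label]
    return GlycanComposition(n_hex=h, n_hexnac=n, n_fuc=n_fuc, n_sia=s)


def generate_dataset(
    n_per_class: int = 100,
    class_mix: Sequence[float] | None = DEFAULT_CLASS_MIX,
    peptides: Sequence[str] = DEFAULT_PEPTIDE_POOL,
    seed: int = 0,
    templates: dict[str, ClassTemplate] | None = None,
    antennarity_bias: float = 0.8,
    source: str = "synthetic",
) -> tuple[list[Spectrum], list[GsmRecord]]:
    """A labelled synthetic GSM data set of ``4 * n_per_class`` spectra.

    With ``class_mix=None`` the classes are balanced; otherwise the total
    is apportioned by the mix (largest-remainder rounding). Compositions
    are drawn so antennarity correlates with class, with the stated bias.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not peptides:
        raise ValueError("empty peptide pool")
    templates = templates or default_templates()
    total = n_per_class * len(CLASS_ORDER)
    if class_mix is None:
        counts = [n_per_class] * len(CLASS_ORDER)
    else:
        mix = np.asarray(class_mix, dtype=float)
        if len(mix) != len(CLASS_ORDER) or mix.sum() <= 0 or (mix < 0).any():
            raise ValueError("class_mix must be 4 non-negative weights")
        mix = mix / mix.sum()
        exact = mix * total
        counts = np.floor(exact).astype(int)
        for i in np.argsort(exact - counts)[::-1][: total - counts.sum()]:
            counts[i] += 1
        counts = counts.tolist()

    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    gsms: list[GsmRecord] = []
    idx = 0
    for label, count in zip(CLASS_ORDER, counts):
        for _ in range(count):
            peptide = peptides[rng.integers(len(peptides))]
            comp = _composition_for(label, rng, antennarity_bias)
            gp = GlycopeptideID(peptide, comp)
            sub_seed = int(rng.integers(2 ** 31))
            spectrum, gsm = generate_gsm(
                templates[label], gp, sub_seed,
                title=f"{source}.{idx:05d}.{label}.{format_glycopeptide_id(gp)}",
                source=source,
            )
            spectra.append(spectrum)
            gsms.append(gsm)
            idx += 1
    return spectra, gsms


def oracle_classify(features: FeatureVector | np.ndarray,
                    threshold: float = 0.0) -> str:
    """Rule-based reference classifier from the diagnostic pairing logic.

    Any B-series fucosylated ion above the threshold is outer evidence; any
    Y-series fucosylated ion is core evidence; both give dual, neither none.
    """
    v = features.values if isinstance(features, FeatureVector) else np.asarray(features)
    index = {l: i for i, l in enumerate(DIAGNOSTIC_ION_ORDER)}
    outer_ev = any(v[index[l]] > threshold for l in B_FUC_IONS)
    core_ev = any(v[index[l]] > threshold for l in Y_FUC_IONS)
    if outer_ev and core_ev:
        return "dual"
    if outer_ev:
        return "outer"
    if core_ev:
        return "core"
    return "none"
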