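"""Synthetic multi-slide cohort generation.

Produces patch-likelihood tables, H&E-like tile images, and on-disk cohorts
with controlled class separability, so every downstream stage (fusion,
signature fitting, evaluation, findings screen) is testable without clinical
data.  All randomness flows through a single integer seed; identical
(spec, seed) pairs produce byte-identical output.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "TextureLaw",
    "FindingSpec",
    "SyntheticSpec",
    "generate_likelihood_table",
    "generate_tile_image",
    "generate_cohort",
    "HEMATOXYLIN_OD",
    "EOSIN_OD",
]

# Published H&E optical-density reference directions (unit-normalized at use).
HEMATOXYLIN_OD = np.array([0.65, 0.70, 0.29])
EOSIN_OD = np.array([0.07, 0.99, 0.11])


@dataclass(frozen=True)
class TextureLaw:
    """Per-class texture parameters for synthetic tiles.

    blob_density: expected number of hematoxylin-like blobs per tile.
    stripe_frequency: spatial frequency (cycles/tile) of the eosin-like field.
    stain_mix: (hematoxylin weight, eosin weight); (0, 0) gives a near-white tile.
    """

    blob_density: float = 12.0
    stripe_frequency: float = 4.0
    stain_mix: tuple[float, float] = (1.0, 0.6)


@dataclass(frozen=True)
class FindingSpec:
    """One binary pathological finding planted on designated likelihood bins.

    ``bins`` are two-decimal likelihood values (e.g. 0.39); the finding is
    drawn from a logistic model on the case-level fraction of tiles whose
    two-decimal token falls in those bins.
    """

    name: str
    prevalence: float = 0.3
    bins: tuple[float, ...] = (0.39, 0.46)
    effect: float = 2.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort draw."""

    n_cases_per_class: dict[str, int] = field(
        default_factory=lambda: {"A": 10, "B": 10}
    )
    slides_per_case: tuple[int, int] = (1, 3)
    tiles_per_slide: tuple[int, int] = (20, 60)
    likelihood_law: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (8.0, 2.0), "B": (2.0, 8.0)}
    )
    texture_law: dict[str, TextureLaw] = field(
        default_factory=lambda: {
            "A": TextureLaw(blob_density=40.0, stripe_frequency=6.0),
            "B": TextureLaw(blob_density=5.0, stripe_frequency=2.0),
        }
    )
    recurrence_rate: float = 0.3
    recurrence_effect: float = 0.0
    findings_model: tuple[FindingSpec, ...] = ()
    positive_class: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cases_per_class:
            raise ValueError("n_cases_per_class must be non-empty")
        for cls, n in self.n_cases_per_class.items():
            if n < 1:
                raise ValueError(f"class {cls!r}: case count must be >= 1, got {n}")
        for name, rng_ in (("slides_per_case", self.slides_per_case),
                           ("tiles_per_slide", self.tiles_per_slide)):
            lo, hi = rng_
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi, got {rng_}")
        for cls in self.n_cases_per_class:
            if cls not in self.likelihood_law:
                raise ValueError(f"no likelihood_law for class {cls!r}")
            a, b = self.likelihood_law[cls]
            if not (a > 0 and b > 0):
                raise ValueError(
                    f"Beta parameters must be > 0, got ({a}, {b}) for class {cls!r}"
                )
        if not 0.0 <= self.recurrence_rate <= 1.0:
            raise ValueError("recurrence_rate must be in [0, 1]")
        for f in self.findings_model:
            if not 0.0 <= f.prevalence <= 1.0:
                raise ValueError(f"finding {f.name!r}: prevalence must be in [0, 1]")

    @property
    def classes(self) -> list[str]:
        return sorted(self.n_cases_per_class)

    @property
    def reference_class(self) -> str:
        """Class whose likelihood the Beta laws describe (default: last)."""
        return self.positive_class or self.classes[-1]


def _sample_beta(rng: np.random.Generator, a: float, b: float, size: int) -> np.ndarray:
    # Degenerate law (huge concentration) collapses to the mean deterministically.
    if a + b > 1e12:
        return np.full(size, a / (a + b))
    return rng.beta(a, b, size=size)


def generate_likelihood_table(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic patch-likelihood table plus its case registry.

    Returns
    -------
    table : DataFrame
        One row per tile: ``case_id, slide_id, col, row, p_<class>..., label``.
        Probability columns lie on the simplex row-wise.
    cohort : DataFrame
        One row per case: ``case_id, class_label, recurrence``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = spec.classes
    ref = spec.reference_class
    if ref not in classes:
        raise ValueError(f"positive_class {ref!r} is not a cohort class")

    case_rows = []
    tile_frames = []
    case_idx = 0
    for cls in classes:
        a, b = spec.likelihood_law[cls]
        for _ in range(spec.n_cases_per_class[cls]):
            case_id = f"case_{case_idx:04d}"
            case_idx += 1
            recurrence = int(rng.random() < spec.recurrence_rate)
            n_slides = int(rng.integers(spec.slides_per_case[0],
                                        spec.slides_per_case[1] + 1))
            for s in range(n_slides):
                slide_id = f"{case_id}_s{s:02d}"
                n_tiles = int(rng.integers(spec.tiles_per_slide[0],
                                           spec.tiles_per_slide[1] + 1))
                p = _sample_beta(rng, a, b, n_tiles)
                if recurrence and spec.recurrence_effect:
                    p = np.clip(p + spec.recurrence_effect, 0.0, 1.0)
                ncol = max(1, math.ceil(math.sqrt(n_tiles)))
                tile_frames.append(_tile_rows(case_id, slide_id, ref, p, classes, ncol))
            case_rows.append({"case_id": case_id, "class_label": cls,
                              "recurrence": recurrence})

    table = pd.concat(tile_frames, ignore_index=True)
    cohort = pd.DataFrame(case_rows)
    return table, cohort


def _tile_rows(case_id: str, slide_id: str, ref: str, p: np.ndarray,
               classes: list[str], ncol: int) -> pd.DataFrame:
    """Expand reference-class likelihoods into simplex rows on a grid.

    Each class's Beta law governs the probability assigned to the designated
    reference (positive) class; the remainder is split uniformly over the
    other classes.
    """
    n = len(p)
    k = len(classes)
    probs = np.empty((n, k))
    own = classes.index(ref)
    if k == 1:
        probs[:, 0] = 1.0
    else:
        rest = (1.0 - p) / (k - 1)
        probs[:] = rest[:, None]
        probs[:, own] = p
    labels = [classes[i] for i in probs.argmax(axis=1)]
    out = {
        "case_id": case_id,
        "slide_id": slide_id,
        "col": np.arange(n) % ncol,
        "row": np.arange(n) // ncol,
    }
    for j, c in enumerate(classes):
        out[f"p_{c}"] = probs[:, j]
    df = pd.DataFrame(out)
    df["label"] = labels
    return df


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter_direction(rng: np.random.Generator, v: np.ndarray,
                      max_deg: float = 5.0) -> np.ndarray:
    """Rotate unit vector v by a random angle <= max_deg toward a random direction."""
    v = _unit(v)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    r = rng.standard_normal(3)
    perp = r - r.dot(v) * v
    nrm = np.linalg.norm(perp)
    if nrm < 1e-12:
        return v
    perp /= nrm
    return _unit(math.cos(angle) * v + math.sin(angle) * perp)


def generate_tile_image(
    texture: TextureLaw,
    seed: int,
    size: int = 512,
    stain_jitter_deg: float = 5.0,
) -> np.ndarray:
    """Render one synthetic H&E-like tile (uint8 RGB, ``size``x``size``).

    Two non-negative stain concentration fields (blobby hematoxylin-like,
    stripy eosin-like) are mixed through Beer-Lambert optical density with
    jittered reference stain directions, so Macenko estimation has a
    recoverable planted structure.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.linspace(0, 1, size), np.linspace(0, 1, size),
                         indexing="ij")

    n_blobs = rng.poisson(texture.blob_density)
    h_field = np.zeros((size, size))
    if n_blobs > 0:
        cx = rng.uniform(0, 1, n_blobs)
        cy = rng.uniform(0, 1, n_blobs)
        sig = rng.uniform(0.02, 0.06, n_blobs)
        amp = rng.uniform(0.5, 1.0, n_blobs)
        for i in range(n_blobs):
            h_field += amp[i] * np.exp(
                -((xx - cx[i]) ** 2 + (yy - cy[i]) ** 2) / (2 * sig[i] ** 2)
            )
    phase = rng.uniform(0, 2 * math.pi)
    theta = rng.uniform(0, math.pi)
    wave = xx * math.cos(theta) + yy * math.sin(theta)
    e_field = 0.5 * (1 + np.sin(2 * math.pi * texture.stripe_frequency * wave + phase))
    e_field += 0.1 * rng.standard_normal((size, size))
    e_field = np.clip(e_field, 0, None)

    w_h, w_e = texture.stain_mix
    h_vec = _jitter_direction(rng, HEMATOXYLIN_OD, stain_jitter_deg)
    e_vec = _jitter_direction(rng, EOSIN_OD, stain_jitter_deg)
    od = (w_h * h_field)[..., None] * h_vec + (w_e * e_field)[..., None] * e_vec
    rgb = 255.0 * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _sample_findings(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    findings: tuple[FindingSpec, ...],
    reference_class: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw binary findings from logistic models on planted fusion features."""
    out = pd.DataFrame({"case_id": cohort["case_id"]})
    if not findings:
        return out
    # Reference-class likelihood per tile, discretized at two decimals: the
    # same scalar the prognostic fusion bins, so the planted truth is a real
    # fusion feature.
    token2 = np.round(table[f"p_{reference_class}"].to_numpy(dtype=float), 2)
    for f in findings:
        if f.prevalence in (0.0, 1.0):
            out[f.name] = int(f.prevalence)
            continue
        in_bins = np.isin(token2, np.round(np.asarray(f.bins), 2))
        frac = (
            pd.Series(in_bins, index=table["case_id"].values)
            .groupby(level=0).mean()
            .reindex(cohort["case_id"].values)
            .fillna(0.0)
            .values
        )
        sd = frac.std()
        z = (frac - frac.mean()) / sd if sd > 0 else np.zeros_like(frac)
        prob = 1.0 / (1.0 + np.exp(-(_logit(f.prevalence) + f.effect * z)))
        out[f.name] = (rng.random(len(prob)) < prob).astype(int)
    return out


def generate_findings(table: pd.DataFrame, cohort: pd.DataFrame,
                      spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the findings table for an already-generated likelihood table."""
    return _sample_findings(table, cohort, spec.findings_model,
                            spec.reference_class,
                            np.random.default_rng(spec.seed + 2))


def generate_cohort(spec: SyntheticSpec, out_dir: str | os.PathLike) -> Path:
    """Materialize a cohort on disk: tile PNGs, labels CSV, findings CSV.

    Layout: ``<out_dir>/<case_id>/<slide_id>/<col>_<row>.png`` plus
    ``labels.csv`` (case_id, slide_id, class_label, recurrence, split — split
    left empty, assigned downstream) and ``findings.csv`` (case_id + one 0/1
    column per finding).
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, cohort = generate_likelihood_table(spec)
    rng = np.random.default_rng(spec.seed + 1)

    cls_of = dict(zip(cohort["case_id"], cohort["class_label"]))
    for (case_id, slide_id), grp in table.groupby(["case_id", "slide_id"], sort=True):
        tex = spec.texture_law[cls_of[case_id]]
        slide_dir = out / str(case_id) / str(slide_id)
        slide_dir.mkdir(parents=True, exist_ok=True)
        for _, r in grp.iterrows():
            tile_seed = int(rng.integers(0, 2**31 - 1))
            img = generate_tile_image(tex, seed=tile_seed)
            Image.fromarray(img).save(slide_dir / f"{int(r['col'])}_{int(r['row'])}.png")

    slides = (
        table[["case_id", "slide_id"]].drop_duplicates().sort_values(
            ["case_id", "slide_id"]
        )
    )
    rec_of = dict(zip(cohort["case_id"], cohort["recurrence"]))
    with open(out / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "slide_id", "class_label", "recurrence", "split"])
        for _, r in slides.iterrows():
            w.writerow([r["case_id"], r["slide_id"], cls_of[r["case_id"]],
                        rec_of[r["case_id"]], ""])

    findings = _sample_findings(table, cohort, spec.findings_model,
                                spec.reference_class,
                                np.random.default_rng(spec.seed + 2))
    findings.to_csv(out / "findings.csv", index=False)
    table.to_csv(out / "likelihoods.csv", index=False)
    return out
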