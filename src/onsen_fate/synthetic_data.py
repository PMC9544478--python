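"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs of the study — segmented rosette photographs, pot-weight
series, whole-genome TIP calls, qPCR plates and the 1001-Genomes SNP
matrix — are either large or unreleased, so each consumer module has a
generator here that emulates its input at a controlled, known truth:

* label images with leaf discs of known painted pixel area (the disc
  assay used to validate pixel counting);
* pot weight series whose daily water loss follows ``a + b*size + noise``;
* TIP tables in the published six-column style with planted context and
  zygosity frequencies;
* ecotype genotype panels with admixture-group structure, a causal SNP of
  stated variance explained, optional duplicated ecotypes, written as a
  GT-only VCF plus CSV sidecars;
* qPCR plates with planted fold changes.

Every generator takes a mandatory seed (or Generator), is bit-reproducible
under it, and returns machine-readable ground truth alongside the data so
tests never re-derive truth from the generated files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import GenotypePanel
from .phenotyping import (
    CLASS_BACKGROUND,
    CLASS_NECROTIC,
    CLASS_SCALE_LABEL,
    CLASS_VITAL,
)
from .tip_catalog import HETEROZYGOUS, HOMOZYGOUS, InsertionRecord

__all__ = [
    "ImageLayout",
    "plan_disc_layout",
    "render_layout",
    "synth_segmentation_image",
    "synth_weight_series",
    "synth_water_loss_table",
    "synth_tip_table",
    "synth_genotype_aridity",
    "write_vcf",
    "synth_qpcr_plate",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Disc-assay label images
# ---------------------------------------------------------------------------


@dataclass
class ImageLayout:
    """Geometry of a synthetic disc-assay scene at base resolution.

    Rendering the same layout at different ``zoom`` factors produces the
    same scene with pixel counts scaled by ``zoom**2`` (up to
    rasterisation), which is exactly what the scale-label calibration must
    undo.
    """

    grid_shape: tuple[int, int]
    disc_radius: float
    label_box: tuple[int, int, int, int]  # row0, col0, height, width
    vital_centers: list[tuple[float, float]]
    necrotic_centers: list[tuple[float, float]]


def plan_disc_layout(
    rng: np.random.Generator,
    k_vital: int,
    k_necrotic: int,
    grid_shape: tuple[int, int] = (400, 400),
    disc_radius: float = 15.0,
    label_shape: tuple[int, int] = (24, 36),
    max_tries: int = 2000,
) -> ImageLayout:
    """Rejection-sample non-overlapping disc centres around a fixed
    corner scale label.  Raises if placement fails within ``max_tries``."""
    h, w = grid_shape
    lh, lw = label_shape
    label_box = (4, 4, lh, lw)
    centers: list[tuple[float, float]] = []
    r = disc_radius
    for _ in range(k_vital + k_necrotic):
        for attempt in range(max_tries):
            cr = rng.uniform(r + 1, h - r - 1)
            cc = rng.uniform(r + 1, w - r - 1)
            # keep clear of the label patch (with one-pixel margin)
            if (
                cr + r >= label_box[0] - 1
                and cr - r <= label_box[0] + lh + 1
                and cc + r >= label_box[1] - 1
                and cc - r <= label_box[1] + lw + 1
            ):
                continue
            if all(np.hypot(cr - a, cc - b) > 2 * r + 2 for a, b in centers):
                centers.append((cr, cc))
                break
        else:
            raise ValueError(
                f"could not place {k_vital + k_necrotic} discs of radius {r} "
                f"on a {grid_shape} grid after {max_tries} tries"
            )
    return ImageLayout(
        grid_shape=grid_shape,
        disc_radius=disc_radius,
        label_box=label_box,
        vital_centers=centers[:k_vital],
        necrotic_centers=centers[k_vital:],
    )


def _paint_disc(
    image: np.ndarray, center: tuple[float, float], radius: float, code: int
) -> int:
    h, w = image.shape
    cr, cc = center
    r0 = max(int(np.floor(cr - radius)) - 1, 0)
    r1 = min(int(np.ceil(cr + radius)) + 2, h)
    c0 = max(int(np.floor(cc - radius)) - 1, 0)
    c1 = min(int(np.ceil(cc + radius)) + 2, w)
    rr, cc_grid = np.meshgrid(
        np.arange(r0, r1) + 0.5, np.arange(c0, c1) + 0.5, indexing="ij"
    )
    mask = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
    image[r0:r1, c0:c1][mask] = code
    return int(mask.sum())


def render_layout(
    layout: ImageLayout,
    zoom: float = 1.0,
    flip_noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Rasterise a layout into an integer label image.

    ``flip_noise`` flips each painted disc pixel to the opposite tissue
    class with the given probability (emulating classifier confusion).
    The returned truth holds exact painted (pre-noise) counts, per-disc
    pixel areas and post-noise counts.
    """
    if flip_noise and rng is None:
        raise ValueError("flip_noise requires an rng")
    h = int(round(layout.grid_shape[0] * zoom))
    w = int(round(layout.grid_shape[1] * zoom))
    image = np.full((h, w), CLASS_BACKGROUND, dtype=np.uint8)
    r0, c0, lh, lw = layout.label_box
    r0z, c0z = int(round(r0 * zoom)), int(round(c0 * zoom))
    lhz, lwz = int(round(lh * zoom)), int(round(lw * zoom))
    image[r0z : r0z + lhz, c0z : c0z + lwz] = CLASS_SCALE_LABEL
    radius = layout.disc_radius * zoom
    disc_areas = {"vital": [], "necrotic": []}
    for code, key, centers in (
        (CLASS_VITAL, "vital", layout.vital_centers),
        (CLASS_NECROTIC, "necrotic", layout.necrotic_centers),
    ):
        for cr, cc in centers:
            disc_areas[key].append(
                _paint_disc(image, (cr * zoom, cc * zoom), radius, code)
            )
    truth = {
        "vital_painted": int(sum(disc_areas["vital"])),
        "necrotic_painted": int(sum(disc_areas["necrotic"])),
        "label_pixels": int(lhz * lwz),
        "disc_areas": disc_areas,
        "zoom": zoom,
    }
    if flip_noise > 0.0:
        painted = np.isin(image, (CLASS_VITAL, CLASS_NECROTIC))
        flip = painted & (rng.random(image.shape) < flip_noise)
        image[flip] = np.where(
            image[flip] == CLASS_VITAL, CLASS_NECROTIC, CLASS_VITAL
        )
    truth["vital_observed"] = int((image == CLASS_VITAL).sum())
    truth["necrotic_observed"] = int((image == CLASS_NECROTIC).sum())
    return image, truth


def synth_segmentation_image(
    seed: int | np.random.Generator,
    k_vital: int,
    k_necrotic: int,
    grid_shape: tuple[int, int] = (400, 400),
    disc_radius: float = 15.0,
    label_shape: tuple[int, int] = (24, 36),
    flip_noise: float = 0.0,
    zoom: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """One synthetic disc-assay label image plus exact ground truth."""
    rng = _rng(seed)
    layout = plan_disc_layout(
        rng, k_vital, k_necrotic, grid_shape, disc_radius, label_shape
    )
    return render_layout(layout, zoom=zoom, flip_noise=flip_noise, rng=rng)


# ---------------------------------------------------------------------------
# Pot weights and water loss
# ---------------------------------------------------------------------------


def synth_weight_series(
    seed: int | np.random.Generator,
    sizes: Sequence[float],
    n_days: int = 8,
    a: float = 2.0,
    b: float = 0.004,
    noise_sd: float = 0.5,
    saturated_weight: float = 300.0,
    dry_weight: float = 100.0,
) -> tuple[pd.DataFrame, dict]:
    """Daily pot weights under size-dependent evaporation.

    Each pot loses ``a + b*size + N(0, noise_sd)`` grams of water per day
    (sizes are vital pixel counts); weights decrease cumulatively from the
    saturated weight and are truncated at the dry weight (truncated pots
    are flagged in the truth record).
    """
    rng = _rng(seed)
    sizes = np.asarray(sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("plant sizes must be positive")
    rows = []
    truncated = []
    for pot, size in enumerate(sizes):
        weight = saturated_weight
        rows.append(
            {"pot": pot, "day": 0, "weight_g": weight, "dry_weight_g": dry_weight}
        )
        for day in range(1, n_days + 1):
            loss = a + b * size + rng.normal(0.0, noise_sd)
            weight = weight - max(loss, 0.0)
            if weight < dry_weight:
                weight = dry_weight
                if pot not in truncated:
                    truncated.append(pot)
            rows.append(
                {"pot": pot, "day": day, "weight_g": weight, "dry_weight_g": dry_weight}
            )
    truth = {
        "a": a,
        "b": b,
        "noise_sd": noise_sd,
        "sizes": sizes.tolist(),
        "saturated_weight": saturated_weight,
        "dry_weight": dry_weight,
        "truncated_pots": truncated,
    }
    return pd.DataFrame(rows), truth


def synth_water_loss_table(
    seed: int | np.random.Generator,
    n_pots: int = 150,
    n_lines: int = 5,
    a: float = 20.0,
    b: float = 0.004,
    line_effect_sd: float = 0.0,
    interaction_sd: float = 0.0,
    noise_sd: float = 2.0,
    size_range: tuple[float, float] = (2000.0, 20000.0),
) -> tuple[pd.DataFrame, dict]:
    """Cumulative-water-loss table for the line/size regression.

    Truth model: ``loss = a + b*size + u_line + v_line*size + noise`` with
    line intercept/slope deviations drawn at the given SDs (0 = no line
    effect, the observed regime in which all lines share one water-use
    law).
    """
    rng = _rng(seed)
    if n_pots < 2 * n_lines:
        raise ValueError("need at least two pots per line")
    lines = [f"line{i}" for i in range(n_lines)]
    u = rng.normal(0.0, line_effect_sd, n_lines) if line_effect_sd > 0 else np.zeros(n_lines)
    v = rng.normal(0.0, interaction_sd, n_lines) if interaction_sd > 0 else np.zeros(n_lines)
    line_idx = np.repeat(np.arange(n_lines), int(np.ceil(n_pots / n_lines)))[:n_pots]
    size = rng.uniform(*size_range, n_pots)
    loss = (
        a
        + b * size
        + u[line_idx]
        + v[line_idx] * size
        + rng.normal(0.0, noise_sd, n_pots)
    )
    df = pd.DataFrame(
        {
            "line": [lines[i] for i in line_idx],
            "vital_pixels": size,
            "water_loss": loss,
        }
    )
    truth = {
        "a": a,
        "b": b,
        "noise_sd": noise_sd,
        "line_intercepts": u.tolist(),
        "line_slopes": v.tolist(),
    }
    return df, truth


# ---------------------------------------------------------------------------
# TIP tables
# ---------------------------------------------------------------------------


def synth_tip_table(
    seed: int | np.random.Generator,
    n: int = 10,
    exon_bias: float = 0.6,
    hom_prob: float = 0.6,
) -> tuple[list[InsertionRecord], dict]:
    """Random TIP catalogue in the published table style.

    ``exon_bias`` is the probability that an insertion lands in an exon
    (ONSEN inserts preferentially into actively transcribed regions);
    the rest split evenly between intron, promoter and TE contexts.
    Zygosity is homozygous with probability ``hom_prob``.
    """
    rng = _rng(seed)
    if not 0.0 <= exon_bias <= 1.0 or not 0.0 <= hom_prob <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    other = ["Intron", "Promoter", "TE"]
    records = []
    contexts = []
    zygosities = []
    for i in range(n):
        context = (
            "Exon" if rng.random() < exon_bias else other[rng.integers(len(other))]
        )
        zygosity = HOMOZYGOUS if rng.random() < hom_prob else HETEROZYGOUS
        chrom = str(rng.integers(1, 6))
        start = int(rng.integers(1_000, 25_000_000))
        records.append(
            InsertionRecord(
                chromosome=chrom,
                start=start,
                end=start + 5,
                context=context,
                gene_id=f"AT{chrom}G{rng.integers(10000, 99999):05d}",
                description=f"synthetic locus {i}",
                zygosity=zygosity,
            )
        )
        contexts.append(context)
        zygosities.append(zygosity)
    truth = {
        "contexts": contexts,
        "zygosities": zygosities,
        "n_exon": sum(c == "Exon" for c in contexts),
        "n_exon_hom": sum(
            c == "Exon" and z == HOMOZYGOUS for c, z in zip(contexts, zygosities)
        ),
    }
    return records, truth


# ---------------------------------------------------------------------------
# Genotype/aridity panels
# ---------------------------------------------------------------------------


def synth_genotype_aridity(
    seed: int | np.random.Generator,
    n_ecotypes: int = 596,
    n_groups: int = 9,
    group_sd: float = 0.45,
    n_snps: int = 11,
    maf_range: tuple[float, float] = (0.3, 0.5),
    causal_ve: float = 4.3,
    resid_sd: float = 1.0,
    causal_index: int = 0,
    n_duplicate_clusters: int = 0,
    duplicates_per_cluster: int = 2,
    missing_rate: float = 0.0,
) -> tuple[GenotypePanel, dict]:
    """Ecotype panel with group structure and one causal SNP.

    Dosages are Hardy–Weinberg binomial draws at per-SNP allele
    frequencies from ``maf_range``.  The causal SNP's effect size beta is
    solved so that its fixed-effect share of the total trait variance
    (the "variance explained") equals ``causal_ve`` percent given the
    realised dosage variance:

        beta^2 = (VE/100) * (sigma_g^2 + sigma_e^2) / ((1 - VE/100) * Var(g)).

    Aridity is ``1 + beta*g + u_group + noise``.  Duplicate clusters
    append exact genotype copies of existing ecotypes (same group and
    aridity, new ids) to exercise kinship pruning; duplicated source ids
    are guaranteed to carry at least one heterozygous site so their KING
    kinship with their copies is exactly 0.5.
    """
    rng = _rng(seed)
    if not 0.0 <= causal_ve < 100.0:
        raise ValueError("causal_ve must lie in [0, 100)")
    if causal_index >= n_snps:
        raise ValueError("causal_index out of range")
    freqs = rng.uniform(*maf_range, n_snps)
    dosages = rng.binomial(2, freqs, size=(n_ecotypes, n_snps)).astype(float)
    g = dosages[:, causal_index]
    var_g = float(np.var(g, ddof=1))
    if var_g == 0.0:
        raise ValueError("causal SNP is monomorphic in this draw; re-seed")
    sigma2_g = group_sd**2
    sigma2_e = resid_sd**2
    if causal_ve > 0.0:
        beta = float(
            np.sqrt(
                (causal_ve / 100.0)
                * (sigma2_g + sigma2_e)
                / ((1.0 - causal_ve / 100.0) * var_g)
            )
        )
    else:
        beta = 0.0
    groups = rng.integers(n_groups, size=n_ecotypes)
    group_effects = rng.normal(0.0, group_sd, n_groups)
    aridity = (
        1.0
        + beta * g
        + group_effects[groups]
        + rng.normal(0.0, resid_sd, n_ecotypes)
    )
    ecotypes = [f"eco{i}" for i in range(n_ecotypes)]
    group_labels = np.array([f"group{gi}" for gi in groups])

    dup_rows = []
    dup_ids = []
    dup_sources = []
    if n_duplicate_clusters:
        has_het = np.where((dosages == 1.0).any(axis=1))[0]
        if len(has_het) < n_duplicate_clusters:
            raise ValueError("not enough heterozygous ecotypes to duplicate")
        sources = has_het[:n_duplicate_clusters]
        for src in sources:
            for j in range(duplicates_per_cluster - 1):
                dup_rows.append(src)
                dup_ids.append(f"{ecotypes[src]}_dup{j}")
            dup_sources.append(ecotypes[src])
    if dup_rows:
        dosages = np.vstack([dosages, dosages[dup_rows]])
        aridity = np.concatenate([aridity, aridity[dup_rows]])
        group_labels = np.concatenate([group_labels, group_labels[dup_rows]])
        ecotypes = ecotypes + dup_ids
    if missing_rate > 0.0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    snp_ids = [f"2_{150000 + 45 * j}" for j in range(n_snps)]
    panel = GenotypePanel(
        ecotypes=ecotypes,
        snp_ids=snp_ids,
        positions=[150000 + 45 * j for j in range(n_snps)],
        dosages=dosages,
        groups=group_labels,
        aridity=aridity,
    )
    truth = {
        "beta": beta,
        "ve_percent": causal_ve,
        "sigma2_group": sigma2_g,
        "sigma2_resid": sigma2_e,
        "causal_snp": snp_ids[causal_index],
        "allele_freqs": freqs.tolist(),
        "duplicate_ids": dup_ids,
        "duplicate_sources": dup_sources,
    }
    return panel, truth


def write_vcf(panel: GenotypePanel, path: str | Path, chrom: str = "2") -> None:
    """Write the panel as a minimal GT-only VCF 4.2 text file."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.ecotypes),
    ]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, (snp, pos) in enumerate(zip(panel.snp_ids, panel.positions)):
        gts = [
            "./." if np.isnan(d) else gt_map[d] for d in panel.dosages[:, j]
        ]
        lines.append(
            f"{chrom}\t{pos}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


def synth_qpcr_plate(
    seed: int | np.random.Generator,
    true_folds: Mapping[str, float],
    control_sample: str = "Col0",
    ct_noise_sd: float = 0.0,
    base_target_ct: float = 22.0,
    base_reference_ct: float = 20.0,
    n_replicates: int = 3,
    target_gene: str = "ONSEN",
    reference_gene: str = "ACTIN2",
) -> tuple[pd.DataFrame, dict]:
    """Long-format Ct table with planted fold changes.

    A sample with fold f amplifies the target log2(f) cycles earlier than
    the control (Ct_target = base − log2(f) + noise); reference-gene Cts
    share a common base.  The control sample (fold 1) is always included.
    """
    rng = _rng(seed)
    folds = dict(true_folds)
    folds.setdefault(control_sample, 1.0)
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be positive")
    rows = []
    for sample, fold in folds.items():
        for rep in range(n_replicates):
            rows.append(
                {
                    "sample": sample,
                    "gene": target_gene,
                    "ct": base_target_ct
                    - np.log2(fold)
                    + rng.normal(0.0, ct_noise_sd),
                    "replicate": rep,
                }
            )
            rows.append(
                {
                    "sample": sample,
                    "gene": reference_gene,
                    "ct": base_reference_ct + rng.normal(0.0, ct_noise_sd),
                    "replicate": rep,
                }
            )
    truth = {"folds": folds, "control": control_sample, "ct_noise_sd": ct_noise_sd}
    return pd.DataFrame(rows), truth
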