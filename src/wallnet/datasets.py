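"""Synthetic expression, probe-level and trait data with planted module structure.

The generator emulates a multi-tissue microarray design: a modest number of
samples (29 by default, matching a whole-plant tissue panel), genes organised
into co-expression modules each driven by a latent per-sample profile, a
minority of unassigned noise genes, and compositional traits (cellulose,
hemicellulose monosaccharides, monolignols) built as linear functions of
chosen module profiles plus Gaussian noise, rescaled onto realistic ranges.

Every downstream stage of the pipeline can therefore be tested against known
ground truth without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitLink",
    "PlantedDesign",
    "GroundTruth",
    "generate_expression",
    "generate_traits",
    "generate_probe_level",
    "default_trait_links",
    "write_design_outputs",
]


@dataclass(frozen=True)
class TraitLink:
    """Specification of one trait as a noisy linear readout of a module profile.

    The generated raw trait is ``c * e_m + eta`` with ``eta ~ N(0, noise_sd^2)``
    where ``e_m`` is the latent profile of planted module ``module`` (1-based).
    The raw values are then mapped onto an output scale: either an explicit
    affine ``scale * raw + offset``, or — when ``target_range`` is given — the
    affine map sending the realised min/max onto that range, which pins the
    trait to a printed compositional range exactly.
    """

    name: str
    module: int
    effect: float = 1.0
    noise_sd: float = 0.3
    unit: str = ""
    scale: float = 1.0
    offset: float = 0.0
    target_range: tuple[float, float] | None = None


def default_trait_links() -> tuple[TraitLink, ...]:
    """Seven cell wall traits on their published compositional ranges.

    Cellulose, xylose and the three monolignols share one driving module
    (the coordinated lignocellulose axis); arabinose and galactose share a
    second (arabinoxylan substitution axis).
    """
    return (
        TraitLink("cellulose", 1, 1.0, 0.3, "% dry matter", target_range=(0.29, 31.33)),
        TraitLink("Xyl", 1, 1.0, 0.3, "mg/g", target_range=(3.49, 245.82)),
        TraitLink("Ara", 2, 1.0, 0.3, "mg/g", target_range=(3.26, 41.07)),
        TraitLink("Gal", 2, 1.0, 0.3, "mg/g", target_range=(0.03, 14.81)),
        TraitLink("H", 1, 1.0, 0.3, "μmol/g", target_range=(4.93, 71.72)),
        TraitLink("G", 1, 1.0, 0.3, "μmol/g", target_range=(1.18, 107.19)),
        TraitLink("S", 1, 1.0, 0.3, "μmol/g", target_range=(1.06, 25.42)),
    )


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-structure generator.

    Defaults describe the reference study conditions used throughout the test
    suite: 29 samples, five modules of 100 genes, 200 noise genes,
    within-module loadings drawn from U(0.6, 0.95) and residual sd 0.5.
    """

    n_samples: int = 29
    module_sizes: tuple[int, ...] = (100, 100, 100, 100, 100)
    n_noise_genes: int = 200
    loading_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 0.5
    random_sign: bool = False
    trait_links: tuple[TraitLink, ...] = field(default_factory=default_trait_links)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if len(self.module_sizes) == 0 or any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes must be non-empty with all sizes >= 1")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must lie within (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure underlying a generated dataset.

    labels: gene -> planted module (0 = noise gene).
    profiles: latent module profiles, modules x samples, zero mean per module.
    trait_links: the link specs the traits were generated from.
    """

    labels: pd.Series
    profiles: pd.DataFrame
    trait_links: tuple[TraitLink, ...]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_expression(design: PlantedDesign) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a genes x samples expression matrix with planted modules.

    Gene ``i`` in module ``m`` is ``w_i * e_m + eps`` with ``w_i`` uniform on
    ``loading_range`` (optionally random-signed), ``eps ~ N(0, noise_sd^2)``;
    noise genes are pure N(0, 1). Latent profiles are i.i.d. standard normal
    over samples, then centred.
    """
    rng = _rng(design.seed, 0)
    n = design.n_samples
    samples = [f"S{j + 1:02d}" for j in range(n)]
    modules = list(range(1, len(design.module_sizes) + 1))

    profiles = rng.standard_normal((len(modules), n))
    profiles -= profiles.mean(axis=1, keepdims=True)
    prof = pd.DataFrame(profiles, index=[f"M{m}" for m in modules], columns=samples)

    rows, ids, labels = [], [], []
    gene_no = 0
    for m, size in zip(modules, design.module_sizes):
        e_m = profiles[m - 1]
        w = rng.uniform(*design.loading_range, size=size)
        if design.random_sign:
            w *= rng.choice([-1.0, 1.0], size=size)
        eps = rng.normal(0.0, design.noise_sd, size=(size, n))
        rows.append(w[:, None] * e_m[None, :] + eps)
        for _ in range(size):
            gene_no += 1
            ids.append(f"G{gene_no:05d}")
            labels.append(m)
    if design.n_noise_genes:
        rows.append(rng.standard_normal((design.n_noise_genes, n)))
        for _ in range(design.n_noise_genes):
            gene_no += 1
            ids.append(f"G{gene_no:05d}")
            labels.append(0)

    expr = pd.DataFrame(np.vstack(rows), index=ids, columns=samples)
    expr.index.name = "gene_id"
    truth = GroundTruth(
        labels=pd.Series(labels, index=ids, name="module"),
        profiles=prof,
        trait_links=design.trait_links,
    )
    return expr, truth


def generate_traits(truth: GroundTruth, design: PlantedDesign) -> pd.DataFrame:
    """Generate a samples x traits table from the planted latent profiles.

    Raw trait ``t`` linked to module ``m`` is ``c_t * e_m + eta`` with
    ``eta ~ N(0, sd_t^2)``, then affinely mapped to its output scale (see
    :class:`TraitLink`). Column units are carried in ``table.attrs['units']``.
    """
    rng = _rng(design.seed, 1)
    n_modules = truth.profiles.shape[0]
    cols, units = {}, {}
    for link in truth.trait_links:
        if not (1 <= link.module <= n_modules):
            raise ValueError(
                f"trait {link.name!r} links to module {link.module}, "
                f"but only modules 1..{n_modules} were planted"
            )
        e_m = truth.profiles.iloc[link.module - 1].to_numpy()
        eta = rng.normal(0.0, link.noise_sd, size=e_m.size)
        raw = link.effect * e_m + eta
        if link.target_range is not None:
            lo, hi = link.target_range
            span = raw.max() - raw.min()
            vals = lo + (raw - raw.min()) * (hi - lo) / span if span > 0 else np.full_like(raw, lo)
        else:
            vals = link.scale * raw + link.offset
        cols[link.name] = vals
        units[link.name] = link.unit
    traits = pd.DataFrame(cols, index=truth.profiles.columns)
    traits.index.name = "sample_id"
    traits.attrs["units"] = units
    return traits


def generate_probe_level(
    expr: pd.DataFrame,
    max_probes_per_gene: int = 3,
    n_negative_controls: int = 50,
    seed: int = 0,
    probe_offset_sd: float = 0.25,
    probe_noise_sd: float = 0.1,
    control_sd_below: float = 3.0,
    control_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Expand a gene matrix into probe rows plus negative-control probes.

    Each gene receives 1..max_probes_per_gene probe rows, each the gene profile
    plus a probe-specific constant offset (N(0, probe_offset_sd^2)) and
    per-sample noise. Negative controls are flat low-intensity rows centred
    ``control_sd_below`` gene-level standard deviations beneath the gene mean;
    they are excluded from the probe->gene map.
    """
    if max_probes_per_gene < 1:
        raise ValueError("max_probes_per_gene must be >= 1")
    if n_negative_controls < 0:
        raise ValueError("n_negative_controls must be >= 0")
    rng = _rng(seed, 2)
    rows, pids, genes = [], [], []
    for gid, profile in zip(expr.index, expr.to_numpy()):
        k = int(rng.integers(1, max_probes_per_gene + 1))
        for p in range(k):
            off = rng.normal(0.0, probe_offset_sd) if probe_offset_sd > 0 else 0.0
            noise = rng.normal(0.0, probe_noise_sd, profile.size) if probe_noise_sd > 0 else 0.0
            rows.append(profile + off + noise)
            pids.append(f"{gid}_p{p + 1}")
            genes.append(gid)
    control_mu = float(np.mean(expr.to_numpy())) - control_sd_below * float(np.std(expr.to_numpy()))
    ctrl_ids = [f"NEG{c + 1:04d}" for c in range(n_negative_controls)]
    for cid in ctrl_ids:
        rows.append(rng.normal(control_mu, control_sd, expr.shape[1]))
        pids.append(cid)
    probes = pd.DataFrame(np.vstack(rows), index=pids, columns=expr.columns)
    probes.index.name = "probe_id"
    p2g = pd.Series(genes, index=pids[: len(genes)], name="gene_id")
    p2g.index.name = "probe_id"
    return probes, p2g, ctrl_ids


def write_design_outputs(
    out_dir: str | Path,
    design: PlantedDesign,
    expr: pd.DataFrame,
    truth: GroundTruth,
    traits: pd.DataFrame | None = None,
    probes: pd.DataFrame | None = None,
    probe_map: pd.Series | None = None,
    control_ids: Sequence[str] | None = None,
) -> Path:
    """Persist a generated dataset as TSV tables plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.to_csv(out / "expression.tsv", sep="\t")
    truth.labels.rename("module").to_csv(out / "truth_labels.tsv", sep="\t")
    sidecar = {
        "design": {**asdict(design), "trait_links": [asdict(l) for l in design.trait_links]},
        "profiles": {m: truth.profiles.loc[m].round(10).tolist() for m in truth.profiles.index},
        "samples": list(truth.profiles.columns),
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1, ensure_ascii=False))
    if traits is not None:
        traits.to_csv(out / "traits.tsv", sep="\t")
    if probes is not None:
        probes.to_csv(out / "probes.tsv", sep="\t")
    if probe_map is not None:
        probe_map.to_csv(out / "probe_to_gene.tsv", sep="\t")
    if control_ids is not None:
        (out / "negative_controls.txt").write_text("\n".join(control_ids) + "\n")
    return out
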