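"""Synthetic pan-cancer datasets with planted ground truth.

The generator emulates the statistical structure the screening cascade
assumes, at desk scale:

* a latent per-sample NET activity ``a_s ~ N(0, 1)`` driving a gene
  signature with a common loading;
* cancer types split into favorable / poor / neutral survival classes,
  with exponential survival whose log hazard is ``gamma_c * a_s`` and a
  class-specific sign for ``gamma_c``;
* planted NET-associated regulatory genes (NRGs) correlated with the
  latent activity only within one survival class (pure noise elsewhere);
* one "key gene" (an SPP1 analog): a poor-class NRG additionally
  over-expressed in poor-class tumors;
* epithelial / mesenchymal programs coupled to the product of NET
  activity and key-gene expression (mesenchymal positively, epithelial
  negatively);
* para-tumor (normal) samples with the signature shifted down.

Every draw is taken from a single ``numpy`` generator seeded from the
config, so a fixed seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSetCollection

__all__ = ["SynthConfig", "SynthTruth", "generate", "null_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings (defaults are the study conditions).

    22 cancer types (6 favorable, 7 poor, 9 neutral), 150 tumors and 20
    para-tumor normals per type, 2000 genes with a 23-gene signature.
    Loadings are population correlations: signature genes correlate with
    the latent activity at ``signature_loading``; planted NRGs at
    ``planted_r`` within their class.  ``key_gene_logfc`` is the key
    gene's extra mean (log2) in poor-class tumors.  Hazards are
    exponential with baseline 1/1000 per day and log hazard
    ``gamma * a_s`` (+0.6 poor, -0.6 favorable, 0 neutral); censoring is
    uniform on [200, 2000] days.
    """

    n_fav: int = 6
    n_poor: int = 7
    n_neutral: int = 9
    samples_per_type: int = 150
    normals_per_type: int = 20
    n_genes: int = 2000
    n_signature: int = 23
    signature_loading: float = 0.8
    n_planted_nrg_per_class: int = 30
    planted_r: float = 0.5
    key_gene_logfc: float = 1.2
    gamma_poor: float = 0.6
    gamma_fav: float = -0.6
    baseline_hazard: float = 1.0 / 1000.0
    censor_low: float = 200.0
    censor_high: float = 2000.0
    emt_coupling: float = 0.5
    n_emt_per_program: int = 15
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fav < 0 or self.n_poor < 0 or self.n_neutral < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_fav + self.n_poor + self.n_neutral < 1:
            raise ValueError("need at least one cancer type")
        for name in ("samples_per_type", "n_genes", "n_signature",
                     "n_planted_nrg_per_class", "n_emt_per_program"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.normals_per_type < 0:
            raise ValueError("normals_per_type must be >= 0")
        for name in ("signature_loading", "planted_r", "emt_coupling"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"|{name}| must be < 1 (it is a correlation)")
        n_special = (self.n_signature + 2 * self.n_planted_nrg_per_class
                     + 2 * self.n_emt_per_program)
        if self.n_genes < n_special + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_special} structured genes"
            )
        if not 0 < self.censor_low < self.censor_high:
            raise ValueError("need 0 < censor_low < censor_high")
        if self.baseline_hazard <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_hazard and noise_sd must be positive")


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    latent: pd.Series
    planted: dict[str, list[str]]
    key_gene: str
    gamma: dict[str, float]
    epithelial: list[str]
    mesenchymal: list[str]

    def to_json(self, path) -> None:
        payload = {
            "latent": {k: float(v) for k, v in self.latent.items()},
            "planted": self.planted,
            "key_gene": self.key_gene,
            "gamma": self.gamma,
            "epithelial": self.epithelial,
            "mesenchymal": self.mesenchymal,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_names(cfg: SynthConfig):
    sig = [f"NETS{i:02d}" for i in range(1, cfg.n_signature + 1)]
    poor = [f"PRG{i:02d}" for i in range(1, cfg.n_planted_nrg_per_class + 1)]
    fav = [f"FRG{i:02d}" for i in range(1, cfg.n_planted_nrg_per_class + 1)]
    mes = [f"MES{i:02d}" for i in range(1, cfg.n_emt_per_program + 1)]
    epi = [f"EPI{i:02d}" for i in range(1, cfg.n_emt_per_program + 1)]
    n_bg = cfg.n_genes - len(sig) - len(poor) - len(fav) - len(mes) - len(epi)
    bg = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    return sig, poor, fav, mes, epi, bg


def generate(cfg: SynthConfig):
    """Draw one synthetic pan-cancer dataset.

    Returns ``(ExpressionMatrix, clinical table, GeneSetCollection,
    SynthTruth)``.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sig, poor_nrg, fav_nrg, mes, epi, bg = _gene_names(cfg)
    genes = sig + poor_nrg + fav_nrg + mes + epi + bg
    key_gene = poor_nrg[0]

    types = (
        [(f"FAV{i:02d}", "favorable", cfg.gamma_fav) for i in range(1, cfg.n_fav + 1)]
        + [(f"POOR{i:02d}", "poor", cfg.gamma_poor) for i in range(1, cfg.n_poor + 1)]
        + [(f"NEUT{i:02d}", "neutral", 0.0) for i in range(1, cfg.n_neutral + 1)]
    )

    sample_ids, cancer_type, tissue, gammas = [], [], [], []
    for name, _cls, gamma in types:
        for i in range(cfg.samples_per_type):
            sample_ids.append(f"{name}_T{i:03d}")
            cancer_type.append(name)
            tissue.append("tumor")
            gammas.append(gamma)
        for i in range(cfg.normals_per_type):
            sample_ids.append(f"{name}_N{i:03d}")
            cancer_type.append(name)
            tissue.append("normal")
            gammas.append(gamma)
    n = len(sample_ids)
    cancer_type = np.array(cancer_type)
    tissue = np.array(tissue)
    gammas = np.array(gammas)
    is_tumor = tissue == "tumor"
    poor_types = {t for t, c, _ in types if c == "poor"}
    fav_types = {t for t, c, _ in types if c == "favorable"}
    in_poor_tumor = is_tumor & np.isin(cancer_type, sorted(poor_types))
    in_fav_tumor = is_tumor & np.isin(cancer_type, sorted(fav_types))

    a = rng.standard_normal(n)  # latent NET activity
    mu = rng.uniform(2.0, 8.0, size=cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    x = np.empty((cfg.n_genes, n))

    def loaded(driver: np.ndarray, loading: float, n_rows: int,
               mask: np.ndarray | None = None) -> np.ndarray:
        """Rows with population correlation ``loading`` to ``driver`` inside
        ``mask`` (pure noise outside)."""
        eps = rng.standard_normal((n_rows, n))
        noise = cfg.noise_sd * eps
        signal = (loading * cfg.noise_sd) * driver[None, :] + np.sqrt(
            max(1.0 - loading**2, 0.0)
        ) * noise
        if mask is None:
            return signal
        return np.where(mask[None, :], signal, noise)

    # signature genes: loaded on a everywhere; para-tumor samples shifted down
    block = loaded(a, cfg.signature_loading, len(sig))
    block[:, ~is_tumor] -= 1.0
    for g, row in zip(sig, block):
        x[gene_pos[g]] = mu[gene_pos[g]] + row

    # class-restricted planted NRGs
    block = loaded(a, cfg.planted_r, len(poor_nrg), mask=in_poor_tumor)
    block[0, in_poor_tumor] += cfg.key_gene_logfc  # the SPP1 analog
    for g, row in zip(poor_nrg, block):
        x[gene_pos[g]] = mu[gene_pos[g]] + row
    block = loaded(a, cfg.planted_r, len(fav_nrg), mask=in_fav_tumor)
    for g, row in zip(fav_nrg, block):
        x[gene_pos[g]] = mu[gene_pos[g]] + row

    # EMT programs: driven by NET activity x key-gene expression
    key_expr = x[gene_pos[key_gene]]
    zkey = (key_expr - key_expr.mean()) / key_expr.std(ddof=1)
    d = a * zkey
    d = (d - d.mean()) / d.std(ddof=1)
    for g, row in zip(mes, loaded(d, cfg.emt_coupling, len(mes))):
        x[gene_pos[g]] = mu[gene_pos[g]] + row
    for g, row in zip(epi, loaded(d, -cfg.emt_coupling, len(epi))):
        x[gene_pos[g]] = mu[gene_pos[g]] + row

    # unstructured background
    bg_rows = [gene_pos[g] for g in bg]
    x[bg_rows] = mu[bg_rows, None] + cfg.noise_sd * rng.standard_normal(
        (len(bg), n)
    )

    # survival for tumor samples: exponential with log-linear hazard in a
    rate = cfg.baseline_hazard * np.exp(gammas * a)
    death = rng.exponential(1.0 / rate)
    censor = rng.uniform(cfg.censor_low, cfg.censor_high, size=n)
    time = np.where(is_tumor, np.minimum(death, censor), np.nan)
    event = np.where(is_tumor, (death <= censor).astype(float), np.nan)

    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=sample_ids))
    clinical = pd.DataFrame(
        {
            "sample": sample_ids,
            "cancer_type": cancer_type,
            "tissue": tissue,
            "time": time,
            "event": event,
            "response": np.nan,
        }
    )

    decoys = {}
    decoy_size = min(25, max(2, len(bg) // 3))
    for i in range(1, 4):
        decoys[f"DECOY_{i}"] = sorted(rng.choice(bg, size=decoy_size, replace=False))
    sets = GeneSetCollection(
        {
            "NET_SIGNATURE": sig,
            "EPITHELIAL": epi,
            "MESENCHYMAL": mes,
            **decoys,
        }
    )
    truth = SynthTruth(
        latent=pd.Series(a, index=sample_ids, name="latent"),
        planted={"poor": list(poor_nrg), "favorable": list(fav_nrg)},
        key_gene=key_gene,
        gamma={name: g for name, _c, g in types},
        epithelial=list(epi),
        mesenchymal=list(mes),
    )
    return expr, clinical, sets, truth


def null_dataset(cfg: SynthConfig):
    """The same layout with every loading, shift, and hazard effect set to
    zero — a type-I-error fixture with no planted structure."""
    flat = replace(
        cfg,
        signature_loading=0.0,
        planted_r=0.0,
        key_gene_logfc=0.0,
        emt_coupling=0.0,
        gamma_poor=0.0,
        gamma_fav=0.0,
    )
    return generate(flat)
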