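"""Desk-scale benchmark experiments.

These drive the directional claims of the method on synthetic data:

* matched-source transfer yields a higher validation AUC than training
  the target network from scratch (non-transfer baseline);
* sliced-Wasserstein distance ranks source domains in the order of
  their constructed similarity (``target_overlap``) to the target;
* the distance ranking anticipates the transfer benefit (more similar
  source, larger AUC gain);
* model ordering: fused TLRM >= image-only TLS >= clinical model.

Problem sizes are deliberately small (48 px patches, width_scale 0.25,
300 patients, three 300-image sources) so a full multi-seed benchmark
runs on one CPU core in minutes; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fixtures, fusion, signature, transfer
from .domain_similarity import embed_images, sliced_w1
from .evaluation import auc

__all__ = ["BenchmarkSettings", "SeedResult", "run_benchmark_seed", "run_benchmark"]

SOURCE_GRID = (
    ("overlap_1.0", "wsi_like", 1.0),
    ("overlap_0.5", "ct_like", 0.5),
    ("overlap_0.0", "natural_like", 0.0),
)


@dataclass(frozen=True)
class BenchmarkSettings:
    n_patients: int = 300
    patch_size: int = 48
    train_fraction: float = 0.7
    width_scale: float = 0.25
    epochs: int = 10
    pretrain_epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    lam: float = 8.0
    source_n: int = 300
    n_projections: int = 64
    screen_alpha: float = 0.05
    max_screened: int = 200  # keep the strongest screened features for SBELM


@dataclass
class SeedResult:
    seed: int
    distances: dict = field(default_factory=dict)  # source name -> sliced W1
    tls_auc: dict = field(default_factory=dict)  # source name / "nontransfer"
    net_auc: dict = field(default_factory=dict)
    tlrm_auc: float = float("nan")
    clinical_auc: float = float("nan")
    gate_mean_final: dict = field(default_factory=dict)


def _fit_tls(model, tr_p, y_tr, va_p, y_va, settings) -> tuple[float, np.ndarray, np.ndarray]:
    fm_tr = transfer.extract_features(model, tr_p)
    fm_va = transfer.extract_features(model, va_p)
    mask, pvals = signature.mannwhitney_filter(fm_tr, y_tr, alpha=settings.screen_alpha)
    if mask.sum() == 0:
        mask = pvals <= np.sort(pvals)[min(9, len(pvals) - 1)]
    keep = np.flatnonzero(mask)
    if len(keep) > settings.max_screened:
        keep = keep[np.argsort(pvals[keep])[: settings.max_screened]]
    ids = [fm_tr.feature_ids[j] for j in keep]
    sb = signature.fit_sbelm(fm_tr.values[:, keep], y_tr, feature_ids=ids)
    sub_tr = signature.FeatureMatrix(fm_tr.values[:, keep], ids, fm_tr.patient_ids)
    sub_va = signature.FeatureMatrix(fm_va.values[:, keep], ids, fm_va.patient_ids)
    s_tr = signature.tls_score(sb, sub_tr)
    s_va = signature.tls_score(sb, sub_va)
    return auc(s_va, y_va), np.asarray(s_tr), np.asarray(s_va)


def pretrain_sources(
    settings: BenchmarkSettings = BenchmarkSettings(), base_seed: int = 1000
) -> dict:
    """Pretrain one source network per source domain (done once, then reused).

    Returns name -> (SourceModel, SourceDomain).
    """
    cfg = transfer.NetworkConfig(
        width_scale=settings.width_scale, input_size=settings.patch_size
    )
    out = {}
    for k, (name, kind, overlap) in enumerate(SOURCE_GRID):
        dom = fixtures.generate_source_domain(
            fixtures.SourceDomainSpec(
                kind=kind, n_classes=3, n=settings.source_n,
                target_overlap=overlap, image_size=settings.patch_size,
                seed=base_seed + 7 * (k + 1),
            )
        )
        src = transfer.pretrain_source(
            dom, None, cfg, seed=base_seed + 13 * (k + 1),
            epochs=settings.pretrain_epochs, batch_size=settings.batch_size,
            lr=settings.lr,
        )
        out[name] = (src, dom)
    return out


def run_benchmark_seed(
    seed: int,
    settings: BenchmarkSettings = BenchmarkSettings(),
    sources: dict | None = None,
) -> SeedResult:
    """One paired run: cohort, three sources, transfer vs non-transfer, fusion."""
    spec = fixtures.SyntheticCohortSpec(
        n=settings.n_patients, patch_size=settings.patch_size, seed=seed
    )
    patches, table = fixtures.generate_target_cohort(spec)
    y = table["label"].to_numpy()
    ids = table["patient_id"].to_numpy()
    rng = np.random.default_rng(seed + 101)
    order = rng.permutation(len(patches))
    n_tr = int(round(settings.train_fraction * len(patches)))
    tr_idx, va_idx = order[:n_tr], order[n_tr:]
    tr_p = [patches[i] for i in tr_idx]
    va_p = [patches[i] for i in va_idx]
    y_tr, y_va = y[tr_idx], y[va_idx]

    cfg = transfer.NetworkConfig(
        width_scale=settings.width_scale, input_size=settings.patch_size
    )
    result = SeedResult(seed=seed)
    target_emb = embed_images(
        np.stack([p.pixels for p in patches]), domain="target"
    )

    if sources is None:
        sources = pretrain_sources(settings)
    tls_scores = {}
    for name, _kind, _overlap in SOURCE_GRID:
        src, dom = sources[name]
        emb_s = embed_images(dom.images, domain=name)
        result.distances[name] = sliced_w1(
            emb_s, target_emb, n_projections=settings.n_projections, seed=seed
        )
        model = transfer.train_target_with_transfer(
            tr_p, y_tr, va_p, y_va, src, cfg, lam=settings.lam, seed=seed,
            epochs=settings.epochs, batch_size=settings.batch_size,
            lr=settings.lr, train_ids=ids[tr_idx], val_ids=ids[va_idx],
        )
        result.net_auc[name] = model.history.val_auc[-1]
        a, s_tr, s_va = _fit_tls(model, tr_p, y_tr, va_p, y_va, settings)
        result.tls_auc[name] = a
        tls_scores[name] = (s_tr, s_va)
        if model.meta is not None:
            gates = [
                float(np.mean(1 / (1 + np.exp(-b)))) for b in model.meta.gate_bias
            ]
            result.gate_mean_final[name] = float(np.mean(gates))

    base = transfer.train_nontransfer(
        tr_p, y_tr, va_p, y_va, cfg, seed=seed, epochs=settings.epochs,
        batch_size=settings.batch_size, lr=settings.lr,
        train_ids=ids[tr_idx], val_ids=ids[va_idx],
    )
    result.net_auc["nontransfer"] = base.history.val_auc[-1]
    a, s_tr, s_va = _fit_tls(base, tr_p, y_tr, va_p, y_va, settings)
    result.tls_auc["nontransfer"] = a
    tls_scores["nontransfer"] = (s_tr, s_va)

    # fusion on the best transfer signature (highest validation AUC)
    best = max(result.distances, key=lambda n: result.tls_auc[n])
    tr_table = table.iloc[tr_idx].reset_index(drop=True)
    va_table = table.iloc[va_idx].reset_index(drop=True)
    screen = fusion.univariate_screen(tr_table, alpha=settings.screen_alpha)
    enc_tr = fusion.encode_clinical(tr_table)
    enc_va = fusion.encode_clinical(va_table)
    enc_tr["tls"] = tls_scores[best][0]
    enc_va["tls"] = tls_scores[best][1]
    cand = [v for v in screen.significant if v in enc_tr.columns] + ["tls"]
    tlrm = fusion.fit_sparse_bayes_lasso(enc_tr[cand], y_tr)
    result.tlrm_auc = auc(fusion.tlrm_score(tlrm, enc_va), y_va)
    clinical = fusion.fit_clinical_logistic(tr_table)
    result.clinical_auc = auc(clinical.predict(enc_va), y_va)
    return result


def run_benchmark(
    seeds, settings: BenchmarkSettings = BenchmarkSettings()
) -> list[SeedResult]:
    """Multi-seed benchmark; the three source networks are pretrained once."""
    sources = pretrain_sources(settings)
    return [run_benchmark_seed(int(s), settings, sources=sources) for s in seeds]
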