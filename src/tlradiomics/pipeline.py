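"""End-to-end experiment orchestration.

A single :class:`RunConfig` drives the whole desk-scale experiment:
synthetic cohort -> patient-level split -> source pretraining ->
transfer training per source (plus the non-transfer baseline) ->
feature extraction -> TLS per source -> source ranking by sliced
Wasserstein distance -> TLRM fusion and the clinical comparator ->
evaluation reports.  A run is a pure function of its config; the
manifest records SHA-256 hashes of every artefact so two runs of the
same config can be compared hash-for-hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures, fusion, signature, transfer
from .domain_similarity import embed_images, sliced_w1
from .errors import ConfigError
from .evaluation import (
    confusion_at,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    idi,
    youden_threshold,
)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline"]


@dataclass(frozen=True)
class SourceEntry:
    name: str = "matched"
    kind: str = "wsi_like"
    n: int = 90
    n_classes: int = 3
    target_overlap: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    """Serialisable description of one experiment."""

    seed: int = 0
    n_patients: int = 160
    prevalence_lac: float = 411 / 573
    patch_size: int = 64
    train_fraction: float = 0.6
    stage_channels: tuple = transfer.DEFAULT_STAGE_CHANNELS
    width_scale: float = 0.25
    declared_feature_width: int | None = None
    epochs: int = 8
    pretrain_epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    lam: float = 1.0
    screen_alpha: float = 0.05
    n_projections: int = 128
    sources: tuple = (
        SourceEntry("wsi_tiles", "wsi_like", 90, 3, 1.0),
        SourceEntry("ct_nodules", "ct_like", 90, 3, 0.5),
        SourceEntry("natural_images", "natural_like", 90, 3, 0.0),
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sources = tuple(
            SourceEntry(**s) if isinstance(s, dict) else s
            for s in raw.pop("sources", cls().sources)
        )
        raw["stage_channels"] = tuple(raw.get("stage_channels",
                                              transfer.DEFAULT_STAGE_CHANNELS))
        return cls(sources=sources, **raw)

    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        payload["stage_channels"] = list(self.stage_channels)
        payload["sources"] = [asdict(s) for s in self.sources]
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def network_config(self) -> transfer.NetworkConfig:
        return transfer.NetworkConfig(
            stage_channels=tuple(self.stage_channels),
            input_size=max(32, self.patch_size),
            n_target_classes=2,
            width_scale=self.width_scale,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns a list of problems (empty = valid)."""
    problems = []
    if config.n_patients < 8:
        problems.append("n_patients must be >= 8")
    if not (0 < config.prevalence_lac < 1):
        problems.append("prevalence_lac must be in (0, 1)")
    if not (0 < config.train_fraction < 1):
        problems.append("train_fraction must be in (0, 1)")
    if config.lam < 0:
        problems.append(f"lambda must be >= 0, got {config.lam}")
    if any(c <= 0 for c in config.stage_channels):
        problems.append("stage_channels must be positive")
    if config.declared_feature_width is not None:
        try:
            width = config.network_config().feature_width
        except Exception as exc:  # invalid network config
            problems.append(str(exc))
            width = None
        if width is not None and width != config.declared_feature_width:
            problems.append(
                f"stage_channels sum to {width} features but "
                f"declared_feature_width is {config.declared_feature_width}"
            )
    if config.patch_size < 32:
        problems.append("patch_size must be >= 32")
    if config.epochs < 1 or config.pretrain_epochs < 0:
        problems.append("epochs must be >= 1 (pretrain_epochs >= 0)")
    names = [s.name for s in config.sources]
    if len(set(names)) != len(names):
        problems.append("source names must be unique")
    return problems


@dataclass
class RunManifest:
    seed: int
    config: dict
    files: dict = field(default_factory=dict)  # path -> sha256
    wall_clock_s: float = 0.0
    stages: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            dict(seed=self.seed, config=self.config, files=self.files,
                 wall_clock_s=self.wall_clock_s, stages=self.stages),
            indent=1, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute the full experiment and write artefacts under ``outdir``."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = RunManifest(seed=config.seed, config=json.loads(
        json.dumps(asdict(config), default=list)))

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.files[name] = _sha256(path)

    # ---- stage: simulate -------------------------------------------------
    spec = fixtures.SyntheticCohortSpec(
        n=config.n_patients, prevalence_lac=config.prevalence_lac,
        patch_size=config.patch_size, seed=config.seed,
    )
    patches, table = fixtures.generate_target_cohort(spec)
    _write("cohort.csv", lambda p: table.to_csv(p, index=False))
    manifest.stages.append("simulate")

    rng = np.random.default_rng(config.seed + 101)
    order = rng.permutation(len(patches))
    n_train = int(round(config.train_fraction * len(patches)))
    tr_idx, va_idx = order[:n_train], order[n_train:]
    y = table["label"].to_numpy()
    ids = table["patient_id"].to_numpy()
    tr_p = [patches[i] for i in tr_idx]
    va_p = [patches[i] for i in va_idx]
    cfg_net = config.network_config()

    # ---- stage: sources --------------------------------------------------
    models: dict[str, transfer.TargetModel] = {}
    tls_models: dict[str, signature.SbelmModel] = {}
    tls_scores: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    distances = {}
    for k, entry in enumerate(config.sources):
        sspec = fixtures.SourceDomainSpec(
            kind=entry.kind, n_classes=entry.n_classes, n=entry.n,
            target_overlap=entry.target_overlap,
            image_size=config.patch_size, seed=config.seed + 7 * (k + 1),
        )
        domain = fixtures.generate_source_domain(sspec)
        src = transfer.pretrain_source(
            domain, None, cfg_net, seed=config.seed + 13 * (k + 1),
            epochs=config.pretrain_epochs, batch_size=config.batch_size,
            lr=config.lr,
        )
        target_imgs = np.stack([p.pixels for p in patches], axis=0)
        emb_t = embed_images(target_imgs, extractor=src, domain="target")
        emb_s = embed_images(domain.images, extractor=src, domain=entry.name)
        distances[entry.name] = sliced_w1(
            emb_s, emb_t, n_projections=config.n_projections, seed=config.seed
        )
        models[entry.name] = transfer.train_target_with_transfer(
            tr_p, y[tr_idx], va_p, y[va_idx], src, cfg_net,
            lam=config.lam, seed=config.seed, epochs=config.epochs,
            batch_size=config.batch_size, lr=config.lr,
            train_ids=ids[tr_idx], val_ids=ids[va_idx],
        )
    label_nontls = "Non-TLS"
    models[label_nontls] = transfer.train_nontransfer(
        tr_p, y[tr_idx], va_p, y[va_idx], cfg_net, seed=config.seed,
        epochs=config.epochs, batch_size=config.batch_size, lr=config.lr,
        train_ids=ids[tr_idx], val_ids=ids[va_idx],
    )
    manifest.stages.append("train")

    ranking = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    _write("source_ranking.json", lambda p: p.write_text(json.dumps(
        [dict(name=n, distance=d, rank=i + 1) for i, (n, d) in enumerate(ranking)],
        indent=1)))

    # ---- stage: signatures ----------------------------------------------
    from .evaluation import auc as _auc

    for name, model in models.items():
        fm_tr = transfer.extract_features(model, tr_p)
        fm_va = transfer.extract_features(model, va_p)
        mask, _ = signature.mannwhitney_filter(fm_tr, y[tr_idx],
                                               alpha=config.screen_alpha)
        if mask.sum() == 0:
            mask = np.ones(fm_tr.values.shape[1], dtype=bool)
        screened_ids = [f for f, m in zip(fm_tr.feature_ids, mask) if m]
        x_tr = fm_tr.select(screened_ids)
        sb = signature.fit_sbelm(x_tr, y[tr_idx], feature_ids=screened_ids)
        tls_models[name] = sb
        s_tr = signature.tls_score(sb, fm_tr)
        s_va = signature.tls_score(sb, fm_va)
        tls_scores[name] = (np.asarray(s_tr), np.asarray(s_va))
    manifest.stages.append("signature")

    tls_val_auc = {n: _auc(s[1], y[va_idx]) for n, s in tls_scores.items()}
    best_source = max(
        (n for n in tls_val_auc if n != label_nontls),
        key=lambda n: tls_val_auc[n],
    )

    # ---- stage: fusion ---------------------------------------------------
    tr_table = table.iloc[tr_idx].reset_index(drop=True)
    va_table = table.iloc[va_idx].reset_index(drop=True)
    screen = fusion.univariate_screen(tr_table, alpha=config.screen_alpha)
    _write("screening.csv", lambda p: screen.to_csv(p))
    enc_tr = fusion.encode_clinical(tr_table)
    enc_va = fusion.encode_clinical(va_table)
    cand_cols = [v for v in screen.significant if v in enc_tr.columns
                 and v not in ("label",)]
    enc_tr["tls"] = tls_scores[best_source][0]
    enc_va["tls"] = tls_scores[best_source][1]
    cand_cols = cand_cols + ["tls"]
    tlrm = fusion.fit_sparse_bayes_lasso(enc_tr[cand_cols], y[tr_idx])
    _write("tlrm.json", lambda p: tlrm.to_json(p))
    clinical = fusion.fit_clinical_logistic(tr_table)
    manifest.stages.append("fusion")

    # ---- stage: evaluate -------------------------------------------------
    model_scores = {
        "clinical": (clinical.predict(enc_tr), clinical.predict(enc_va)),
        f"TLS-{best_source}": tls_scores[best_source],
        "Non-TLS": tls_scores[label_nontls],
        "TLRM": (fusion.tlrm_score(tlrm, enc_tr), fusion.tlrm_score(tlrm, enc_va)),
    }
    for name in tls_scores:
        if name not in (best_source, label_nontls):
            model_scores[f"TLS-{name}"] = tls_scores[name]

    reports = []
    for name, (s_tr, s_va) in model_scores.items():
        thr = youden_threshold(s_tr, y[tr_idx])
        rep_tr = confusion_at(s_tr, y[tr_idx], thr, cohort="train")
        rep_va = confusion_at(s_va, y[va_idx], thr, cohort="validation")
        for rep in (rep_tr, rep_va):
            row = rep.as_dict()
            row["model"] = name
            reports.append(row)
    _write("eval_reports.csv",
           lambda p: pd.DataFrame(reports).to_csv(p, index=False))

    comparisons = []
    tlrm_va = model_scores["TLRM"][1]
    for other in ("clinical", f"TLS-{best_source}"):
        z, p_dl = delong_test(tlrm_va, model_scores[other][1], y[va_idx])
        idi_val, p_idi = idi(model_scores[other][1], tlrm_va, y[va_idx])
        comparisons.append(dict(model_new="TLRM", model_old=other,
                                delong_z=z, delong_p=p_dl, idi=idi_val,
                                idi_p=p_idi))
    hl_groups = int(min(10, max(3, len(va_idx) // 3)))
    hl_chi2, hl_p = hosmer_lemeshow(tlrm_va, y[va_idx], g=hl_groups)
    _write("comparisons.json", lambda p: p.write_text(json.dumps(
        dict(comparisons=comparisons,
             hosmer_lemeshow=dict(chi2=hl_chi2, p=hl_p),
             tls_val_auc=tls_val_auc, best_source=best_source,
             distances=distances), indent=1, sort_keys=True)))
    dca = decision_curve(tlrm_va, y[va_idx])
    _write("decision_curve.csv", lambda p: dca.to_csv(p, index=False))
    manifest.stages.append("evaluate")

    manifest.wall_clock_s = time.time() - t0
    manifest.to_json(outdir / "manifest.json")
    return manifest
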