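"""End-to-end imputation: window planning and the imputation model objects.

Two model classes cover the two workflows:

* ``GeneralImputation`` — fill sporadic (and any systematic) gaps in a
  target at the loci it shares with the reference panel.
* ``ReconstructiveImputation`` — reconstruct a population at the union of
  its own chip positions and another population's chip positions,
  restricted to the panel: output loci = (A ∪ B) ∩ P. Loci on the other
  chip but not the target's (B \\ A) enter as fully missing (systematic)
  columns before window planning.

``two_way_impute`` runs two independent one-way reconstructions so both
populations end up on the identical (A ∪ B) ∩ P marker set.

Chromosomes are trained in sliding windows (default 1000 markers). The
terminal remainder is handled by a reverse window anchored at the last
marker and extending backward a full window; its predictions are used
only for the remainder markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    MarkerRecord,
    PositionSet,
    subset_panel,
)
from .matching import general_mask_augment, random_mask, reconstructive_mask
from .model import NetworkConfig, predict_window, train_window

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "ImputationResult",
    "plan_windows",
    "GeneralImputation",
    "ReconstructiveImputation",
    "general_impute",
    "reconstructive_impute",
    "two_way_impute",
]


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous marker span: the model trains on train_span and its
    predictions are used on impute_span (a suffix of train_span for the
    reverse terminal window)."""

    chrom: str
    train_span: tuple[int, int]
    impute_span: tuple[int, int]
    reverse: bool = False

    def __post_init__(self) -> None:
        ts, ie = self.train_span, self.impute_span
        if not (ts[0] <= ie[0] and ie[1] <= ts[1]):
            raise ValueError("impute_span must lie within train_span")


def plan_windows(p: int, window: int) -> list[WindowSpec]:
    """Forward full windows plus one reverse terminal window for the remainder.

    For p markers and window size w: forward windows [0,w), [w,2w), ... for
    every full multiple; a remainder r > 0 is imputed by a reverse window
    training on [p-w, p) but imputing only [p-r, p). A chromosome shorter
    than w gets a single window covering all markers.
    """
    if window < 1:
        raise ValueError("window size must be >= 1")
    if p < 1:
        raise ValueError("need at least one marker")
    if p <= window:
        return [WindowSpec("", (0, p), (0, p))]
    specs = []
    full = p // window
    for i in range(full):
        span = (i * window, (i + 1) * window)
        specs.append(WindowSpec("", span, span))
    r = p - full * window
    if r > 0:
        specs.append(WindowSpec("", (p - window, p), (p - r, p), reverse=True))
    return specs


@dataclass
class ImputationResult:
    """A complete genotype matrix with provenance and per-run accounting.

    provenance is True where the entry was imputed, False where the input
    genotype passed through unchanged. ``summary()`` prints the report.
    """

    genotypes: GenotypeMatrix
    provenance: np.ndarray
    report: dict
    window_models: list = field(default_factory=list)

    def summary(self) -> str:
        rep = self.report
        lines = [
            "Imputation result",
            "-----------------",
            f"samples              : {self.genotypes.n_samples}",
            f"markers              : {self.genotypes.n_markers}",
            f"windows trained      : {rep.get('n_windows')}",
            f"entries imputed      : {rep.get('n_imputed')}",
            f"input missing rate   : {rep.get('input_missing_rate'):.4f}",
            f"dropped target loci  : {rep.get('n_dropped_target_loci', 0)}",
        ]
        return "\n".join(lines)


def _impute_windows(
    target: GenotypeMatrix,
    panel: GenotypeMatrix,
    cfg: NetworkConfig,
    mode: str,
) -> tuple[GenotypeMatrix, np.ndarray, list]:
    """Shared per-window train/predict loop; mode is 'general' or
    'reconstructive' (controls masking/augmentation)."""
    windows = plan_windows(target.n_markers, cfg.window)
    out = target.codes.copy()
    models = []
    rng = np.random.default_rng(cfg.seed)
    for wi, spec in enumerate(windows):
        a, b = spec.train_span
        tr_w = panel.marker_slice(a, b)
        te_w = target.marker_slice(a, b)
        wseed = int(rng.integers(0, 2**31 - 1))

        if not (te_w.codes == MISSING).any():
            logger.info("window %d/%d: nothing to impute", wi + 1, len(windows))
            continue

        if not cfg.matching:
            _, corrupted = random_mask(tr_w, te_w, np.random.default_rng(wseed))
            clean = tr_w.codes
            corrupted = corrupted.codes
        elif mode == "general" and cfg.augmentation and te_w.n_samples >= 2:
            try:
                aug = general_mask_augment(tr_w, te_w, k=min(cfg.knn_k, te_w.n_samples - 1))
                clean, corrupted = aug.clean, aug.corrupted
            except ValueError as exc:
                # e.g. a marker missing in every sample: KNN cannot vote, so
                # train this window without the augmented rows
                logger.warning("window %d: augmentation skipped (%s)", wi + 1, exc)
                _, corr = reconstructive_mask(tr_w, te_w)
                clean, corrupted = tr_w.codes, corr.codes
        else:
            _, corr = reconstructive_mask(tr_w, te_w)
            clean, corrupted = tr_w.codes, corr.codes

        mr = float((corrupted == MISSING).mean())
        wcfg = replace(cfg.with_dropout_for(mr), seed=wseed)
        model = train_window(clean, corrupted, wcfg)
        model.window = spec
        models.append(model)

        pred = predict_window(model, te_w.codes)
        ia, ib = spec.impute_span
        out[:, ia:ib] = np.where(
            target.codes[:, ia:ib] == MISSING, pred[:, ia - a : ib - a], target.codes[:, ia:ib]
        )
        logger.info(
            "window %d/%d [%d,%d)%s: trained %d epochs, best loss %.4f",
            wi + 1, len(windows), a, b, " (reverse)" if spec.reverse else "",
            model.epochs_run, model.best_loss,
        )
    provenance = target.codes == MISSING
    g = GenotypeMatrix(target.sample_ids, target.markers, out, validate=False)
    return g, provenance, models


class GeneralImputation:
    """Panel-based imputation of the loci shared by target and panel.

    Parameters
    ----------
    target : genotypes to impute (codes 0/1/2/3; 0 = missing).
    panel : missing-free reference panel.
    cfg : network and training configuration.
    """

    def __init__(
        self, target: GenotypeMatrix, panel: GenotypeMatrix, cfg: NetworkConfig | None = None
    ) -> None:
        self.cfg = cfg if cfg is not None else NetworkConfig()
        shared = target.position_set() & panel.position_set()
        if len(shared) == 0:
            raise ValueError("target and panel share no loci")
        panel_sub = subset_panel(panel, shared, target_markers=target.markers)
        shared_after = panel_sub.position_set()
        keep = [j for j, m in enumerate(target.markers) if m.key in shared_after]
        self.n_dropped = target.n_markers - len(keep)
        if self.n_dropped:
            logger.info("dropping %d target loci absent from the panel", self.n_dropped)
        self.target = target.subset_markers(keep)
        self.panel = panel_sub

    def fit(self, seed: int | None = None) -> ImputationResult:
        cfg = self.cfg if seed is None else replace(self.cfg, seed=seed)
        g, prov, models = _impute_windows(self.target, self.panel, cfg, mode="general")
        report = {
            "n_windows": len(models),
            "n_imputed": int(prov.sum()),
            "input_missing_rate": self.target.missing_rate(),
            "n_dropped_target_loci": self.n_dropped,
        }
        return ImputationResult(g, prov, report, models)


class ReconstructiveImputation:
    """One-way reconstruction of pop1 at (A ∪ B) ∩ P.

    A is pop1's marker set, B the guiding position set (population II's
    chip), P the panel's loci. Loci in B \\ A are appended as systematic
    missing columns (panel ref/alt metadata) before window planning; the
    matching algorithm then drives training in every window.
    """

    def __init__(
        self,
        pop1: GenotypeMatrix,
        positions2: PositionSet,
        panel: GenotypeMatrix,
        cfg: NetworkConfig | None = None,
    ) -> None:
        self.cfg = cfg if cfg is not None else NetworkConfig()
        a = pop1.position_set()
        union = a | positions2
        panel_sub = subset_panel(panel, union, target_markers=pop1.markers)
        out_keys = panel_sub.position_set()
        if len(out_keys) == 0:
            raise ValueError("(A ∪ B) ∩ P is empty")

        # assemble the target over (A∪B)∩P in panel (sorted) marker order
        code_of = {m.key: j for j, m in enumerate(pop1.markers)}
        n = pop1.n_samples
        cols = np.zeros((n, panel_sub.n_markers), dtype=np.int8)
        n_appended = 0
        for j, m in enumerate(panel_sub.markers):
            src = code_of.get(m.key)
            if src is not None:
                cols[:, j] = pop1.codes[:, src]
            else:
                n_appended += 1  # B \ A: systematic missing column
        self.n_appended = n_appended
        self.target = GenotypeMatrix(pop1.sample_ids, list(panel_sub.markers), cols, validate=False)
        self.panel = panel_sub

    def fit(self, seed: int | None = None) -> ImputationResult:
        cfg = self.cfg if seed is None else replace(self.cfg, seed=seed)
        g, prov, models = _impute_windows(self.target, self.panel, cfg, mode="reconstructive")
        report = {
            "n_windows": len(models),
            "n_imputed": int(prov.sum()),
            "input_missing_rate": self.target.missing_rate(),
            "n_systematic_columns": self.n_appended,
        }
        return ImputationResult(g, prov, report, models)


def general_impute(
    target: GenotypeMatrix, panel: GenotypeMatrix, cfg: NetworkConfig | None = None
) -> ImputationResult:
    """Functional wrapper around GeneralImputation(...).fit()."""
    return GeneralImputation(target, panel, cfg).fit()


def reconstructive_impute(
    pop1: GenotypeMatrix,
    positions2: PositionSet,
    panel: GenotypeMatrix,
    cfg: NetworkConfig | None = None,
) -> ImputationResult:
    """Functional wrapper around ReconstructiveImputation(...).fit()."""
    return ReconstructiveImputation(pop1, positions2, panel, cfg).fit()


def two_way_impute(
    pop1: GenotypeMatrix,
    pop2: GenotypeMatrix,
    panel: GenotypeMatrix,
    cfg: NetworkConfig | None = None,
) -> tuple[ImputationResult, ImputationResult]:
    """Two independent one-way reconstructions: pop1 guided by pop2's
    positions and pop2 guided by pop1's; both outputs carry the identical
    (A ∪ B) ∩ P marker key set."""
    r1 = reconstructive_impute(pop1, pop2.position_set(), panel, cfg)
    r2 = reconstructive_impute(pop2, pop1.position_set(), panel, cfg)
    return r1, r2
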