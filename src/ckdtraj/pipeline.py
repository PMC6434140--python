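"""End-to-end pipeline: cohort generation -> staging -> trajectory ->
per-year Bayesian networks -> per-year SVM models, with a JSON manifest.

A single global seed is expanded into independent per-stage child seeds
through ``numpy.random.SeedSequence`` with fixed per-stage spawn keys, so
adding a stage never perturbs the randomness of earlier stages and the
whole run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesnet import CKDBayesNet, build_bn_dataset, discretize_by_roc
from .cohort import CohortConfig, generate_cohort
from .io import read_cohort_csv, records_to_frame, write_cohort_csv
from .staging import PrognosticCategory, stage_cohort
from .svm import RiskSVM, SplitProtocol
from .trajectory import (
    ALL_STAGES,
    category_counts_by_year,
    mean_vectors_by_stage,
    transition_matrix,
)

log = logging.getLogger(__name__)

# fixed spawn keys: new stages must append, never renumber
_STAGE_KEYS = {"cohort": 0, "bn": 1, "svm": 2}


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; nested configs validate themselves."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    outcome_rule: str = "very_high_at_end"
    cutoffs: dict | str = "default"     # mapping, "default", or "fit" (ROC)
    bn_alpha: float = 0.05
    bn_replicates: int = 200
    bn_threshold: float = 0.5
    svm_c: float = 1.0
    svm_gamma: float | None = None
    train_fraction: float = 2.0 / 3.0
    cv_folds: int = 3
    outdir: str = "ckdtraj_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def child_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed,
                                    spawn_key=(_STAGE_KEYS[stage],))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g",
              lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write every artifact under
    ``config.outdir``; returns the run manifest (also written as JSON).

    Artifacts: ``cohort.csv``, ``staging.csv``, ``stage_grid_<y0>.tsv``
    (4 x 4 baseline stage counts), ``category_counts.tsv``,
    ``transitions_<y0>_<y>.tsv``, ``mean_vectors_<y0>_<y1>.tsv``,
    ``bn_<year>.tsv`` / ``bn_<year>.dot``, ``svm_errors.tsv`` and
    ``possibility_<year>.tsv``, plus ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "counts": {}}

    def stage_guard(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except Exception as exc:  # noqa: BLE001 - report and re-raise
                manifest["stages"][name] = f"failed: {exc}"
                _dump_manifest(manifest, outdir)
                log.error("stage %s failed: %s", name, exc)
                raise
        return deco

    state: dict = {}

    @stage_guard("generate")
    def _generate():
        cohort_cfg = dataclasses.replace(config.cohort,
                                         seed=config.child_seed("cohort"))
        records = generate_cohort(cohort_cfg)
        write_cohort_csv(records, outdir / "cohort.csv")
        state["cohort"] = records_to_frame(records)
        manifest["counts"]["subject_years"] = len(records)
        manifest["counts"]["subjects"] = int(
            state["cohort"]["subject_id"].nunique())

    @stage_guard("stage")
    def _stage():
        staged = stage_cohort(state["cohort"])
        staged.to_csv(outdir / "staging.csv", index=False,
                      float_format="%.10g", lineterminator="\n")
        state["staged"] = staged
        y0 = int(staged["year"].min())
        state["y0"] = y0
        state["yf"] = int(staged["year"].max())
        base = staged[staged["year"] == y0]
        grid = np.zeros((4, 4), dtype=int)
        np.add.at(grid, (base["g"].to_numpy(), base["p"].to_numpy()), 1)
        _write_tsv(pd.DataFrame(grid,
                                index=["G1", "G2", "G3a", "G3b"],
                                columns=["neg", "trace", "1+", "2+"]),
                   outdir / f"stage_grid_{y0}.tsv", index=True)
        _write_tsv(category_counts_by_year(staged),
                   outdir / "category_counts.tsv")
        manifest["counts"]["baseline_n"] = int(len(base))

    @stage_guard("trajectory")
    def _trajectory():
        staged, y0, yf = state["staged"], state["y0"], state["yf"]
        years = sorted(int(y) for y in staged["year"].unique())
        pair_n = {}
        for y in years[1:]:
            tm = transition_matrix(staged, y0, y)
            _write_tsv(tm.to_frame(), outdir / f"transitions_{y0}_{y}.tsv",
                       index=True)
            pair_n[str(y)] = tm.n
        mv = mean_vectors_by_stage(staged, y0, yf)
        rows = [{"stage": str(s), "g": s.coord()[0], "p": s.coord()[1],
                 "dg": v.dg, "dp": v.dp} for s, v in sorted(mv.items())]
        _write_tsv(pd.DataFrame(rows), outdir / f"mean_vectors_{y0}_{yf}.tsv")
        manifest["counts"]["complete_pairs"] = pair_n

    @stage_guard("bn")
    def _bn():
        staged, y0, yf = state["staged"], state["y0"], state["yf"]
        cutoffs = _resolve_cutoffs(config, state)
        manifest["cutoffs"] = cutoffs
        seed = config.child_seed("bn")
        years = sorted(int(y) for y in staged["year"].unique())
        for y in [y for y in years if y0 < y < yf]:
            data = build_bn_dataset(state["cohort"], staged, y0, y, yf,
                                    cutoffs, config.outcome_rule)
            res = CKDBayesNet(data, alpha=config.bn_alpha).fit(
                B=config.bn_replicates, threshold=config.bn_threshold,
                seed=seed)
            _write_tsv(res.network.edge_frame(), outdir / f"bn_{y}.tsv")
            (outdir / f"bn_{y}.dot").write_text(res.network.to_dot())

    @stage_guard("svm")
    def _svm():
        staged, y0, yf = state["staged"], state["y0"], state["yf"]
        seed = config.child_seed("svm")
        protocol = SplitProtocol(train_fraction=config.train_fraction,
                                 cv_folds=config.cv_folds, seed=seed)
        years = sorted(int(y) for y in staged["year"].unique())
        rows = []
        for y in [y for y in years if y0 < y < yf]:
            res = RiskSVM(staged, y0, y, yf, protocol, config.svm_c,
                          config.svm_gamma, config.outcome_rule).fit()
            rows.append({"model": f"Model {y0} + {y}",
                         "training_error": res.training_error,
                         "test_error": res.test_error})
            grid = pd.DataFrame(
                res.possibility_grid,
                index=[c.name for c in PrognosticCategory],
                columns=[c.name for c in PrognosticCategory])
            _write_tsv(grid, outdir / f"possibility_{y}.tsv", index=True)
        _write_tsv(pd.DataFrame(rows), outdir / "svm_errors.tsv")

    _dump_manifest(manifest, outdir)
    return manifest


def _resolve_cutoffs(config: PipelineConfig, state: dict) -> dict:
    from .bayesnet import DEFAULT_CUTOFFS
    if isinstance(config.cutoffs, dict):
        return dict(DEFAULT_CUTOFFS, **config.cutoffs)
    if config.cutoffs == "default":
        return dict(DEFAULT_CUTOFFS)
    if config.cutoffs != "fit":
        raise ValueError("cutoffs must be a mapping, 'default' or 'fit'")
    # ROC-fitted on baseline-year values against the outcome
    from .staging import outcome as outcome_fn
    staged, y0, yf = state["staged"], state["y0"], state["yf"]
    c0 = staged[staged["year"] == y0].set_index("subject_id")["category"]
    cf = staged[staged["year"] == yf].set_index("subject_id")["category"]
    ids = c0.index.intersection(cf.index)
    flags = pd.Series(
        [int(outcome_fn(PrognosticCategory(int(c0[i])),
                        PrognosticCategory(int(cf[i])), config.outcome_rule))
         for i in ids], index=ids)
    base = state["cohort"][state["cohort"]["year"] == y0] \
        .set_index("subject_id").loc[ids]
    return {var: discretize_by_roc(base[var].to_numpy(), flags.to_numpy())
            for var in ("age", "bmi", "waist")}


def _dump_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
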