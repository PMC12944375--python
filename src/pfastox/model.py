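"""Top-level modelling facade: ReadAcrossModel -> fit() -> ReadAcrossResults.

``ReadAcrossModel`` is constructed from a labelled dataset (compound
records plus descriptor matrix) and holds the workflow configuration;
``fit()`` executes the pipeline

    stratified split -> repeated-value filter -> duplicate removal ->
    z-score (train parameters) -> Boruta selection -> grid-search autoML
    with stratified CV -> final estimator -> applicability domain ->
    held-out evaluation

and returns a ``ReadAcrossResults`` object carrying every fitted artefact,
the held-out metrics, per-query predictions with neighbour evidence, and
``summary()`` / ``predict()`` / ``explain()`` / cross-validation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .appdomain import ADModel, ad_check, ad_fit
from .boruta import BorutaConfig, BorutaResult, boruta_select
from .dataset_io import (
    CompoundRecord,
    DescriptorMatrix,
    LabeledDataset,
    ToxClass,
    ValidationError,
    assign_toxicity_class,
)
from .explain import (
    ReadAcrossReport,
    ShapleyExplanation,
    global_importance,
    read_across_report,
    shapley_exact,
)
from .models import (
    EstimatorSpec,
    FittedEstimator,
    GridSearchResult,
    KNNModel,
    PredictionRecord,
    default_grids,
    grid_search_cv,
    knn_fit,
    knn_predict,
    train_estimator,
)
from .preprocess import (
    ColumnFilterResult,
    DuplicateReport,
    Normalizer,
    SplitResult,
    drop_duplicate_rows,
    filter_repeated_columns,
    stratified_split,
    zscore_apply,
    zscore_fit,
)
from .validate import (
    ConfusionMatrix,
    CVReport,
    MetricsReport,
    YRandReport,
    confusion,
    kfold_cv,
    metrics,
    y_randomization,
)


def _apply_selected(
    norm: Normalizer, selected: Sequence[str], descriptors
) -> DescriptorMatrix:
    """z-score a query table on the selected features only.

    Queries must carry at least the selected columns; extra columns are
    ignored.  The stored z-score parameters (train-derived) are subset
    accordingly.
    """
    if isinstance(descriptors, pd.DataFrame):
        descriptors = DescriptorMatrix(descriptors)
    missing = [c for c in selected if c not in descriptors.column_names]
    if missing:
        raise ValidationError(
            f"query descriptors lack selected columns {missing}"
        )
    cols = list(selected)
    sub = Normalizer(mean=norm.mean[cols], sd=norm.sd[cols],
                     fitted_on=norm.fitted_on, ddof=norm.ddof)
    return zscore_apply(sub, descriptors.select_columns(cols))


class ReadAcrossModel:
    """Binary toxicity read-across classifier over a descriptor table.

    Parameters
    ----------
    dataset : LabeledDataset
        Compound records (LD50 and/or class) with their descriptor matrix.
        Records carrying an LD50 but no class are classified with the
        ``ld50_threshold`` rule (low iff LD50 > threshold).
    test_fraction : float
        Held-out share for the stratified split (default 0.3).
    max_repeat_fraction : float
        Repeated-value column filter budget (default 0.2).
    families : sequence of str
        Model families entered into the grid search (default ``("knn",)``;
        any of knn, random_forest, xgboost, neural_network).
    grids : mapping family -> EstimatorSpec, optional
        Search ranges; defaults to the reproduction grids.
    boruta : BorutaConfig, optional
    include_tentative : bool
        Whether Boruta-tentative features enter the final model.
    cv_folds : int
        Folds for the model-selection cross-validation (default 5).
    ad_Z : float
        Applicability-domain cutoff constant (default 0.5).
    positive_class : ToxClass
        Metrics convention (default low toxicity).
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        test_fraction: float = 0.3,
        max_repeat_fraction: float = 0.2,
        families: Sequence[str] = ("knn",),
        grids: Mapping[str, EstimatorSpec] | None = None,
        boruta: BorutaConfig | None = None,
        include_tentative: bool = False,
        cv_folds: int = 5,
        ad_Z: float = 0.5,
        ld50_threshold: float = 500.0,
        positive_class: ToxClass = ToxClass.LOW,
    ):
        records = []
        for r in dataset.records:
            if r.tox_class is None and r.ld50 is not None:
                r = CompoundRecord(r.id, r.smiles, r.name, r.mw, r.ld50,
                                   assign_toxicity_class(r.ld50, ld50_threshold))
            records.append(r)
        unlabelled = [r.id for r in records if r.tox_class is None]
        if unlabelled:
            raise ValidationError(
                f"records without LD50 or class cannot train: {unlabelled[:5]}"
            )
        self.dataset = LabeledDataset(records, dataset.descriptors)
        self.test_fraction = test_fraction
        self.max_repeat_fraction = max_repeat_fraction
        self.families = tuple(families)
        all_grids = default_grids()
        if grids:
            all_grids.update(grids)
        self.grids = all_grids
        self.boruta_config = boruta
        self.include_tentative = include_tentative
        self.cv_folds = cv_folds
        self.ad_Z = ad_Z
        self.positive_class = positive_class

    @classmethod
    def from_dataframe(
        cls,
        descriptors: pd.DataFrame,
        labels: Mapping[str, ToxClass] | Sequence,
        smiles: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "ReadAcrossModel":
        """Build directly from a descriptor DataFrame and labels."""
        ids = [str(i) for i in descriptors.index]
        if not isinstance(labels, Mapping):
            labels = dict(zip(ids, labels))
        records = [
            CompoundRecord(
                id=i,
                smiles=(smiles or {}).get(i, ""),
                tox_class=labels[i],
            )
            for i in ids
        ]
        df = descriptors.copy()
        df.index = ids
        return cls(LabeledDataset(records, DescriptorMatrix(df)), **kwargs)

    def fit(self, seed: int = 0) -> "ReadAcrossResults":
        """Run the full pipeline and return the fitted results object."""
        ds = self.dataset
        labels = ds.labels()
        desc_ids = set(ds.descriptors.row_ids)
        usable = {i: labels[i] for i in ds.descriptors.row_ids}
        if len(usable) < len(labels):
            missing = sorted(set(labels) - desc_ids)
            raise ValidationError(f"no descriptors for records {missing[:5]}")

        split = stratified_split(usable, self.test_fraction, seed)
        X_train = ds.descriptors.select_rows(split.train_ids)
        X_test = ds.descriptors.select_rows(split.test_ids)

        filt = filter_repeated_columns(X_train, self.max_repeat_fraction)
        if not filt.kept:
            raise ValidationError("repeated-value filter removed every column")
        X_train = X_train.select_columns(filt.kept)
        X_test = X_test.select_columns(filt.kept)

        X_train, dup_report = drop_duplicate_rows(X_train, usable)
        train_ids = X_train.row_ids

        norm = zscore_fit(X_train)
        Xtr_z = zscore_apply(norm, X_train)
        Xte_z = zscore_apply(norm, X_test)

        bconf = self.boruta_config or BorutaConfig(seed=seed)
        boruta_res = boruta_select(Xtr_z, usable, bconf)
        selected = list(boruta_res.confirmed)
        if self.include_tentative:
            selected += boruta_res.tentative
        if not selected:
            # nothing confirmed: fall back to tentative so a model still fits
            selected = boruta_res.tentative or filt.kept
        selected = [c for c in Xtr_z.column_names if c in set(selected)]
        Xtr_sel = Xtr_z.select_columns(selected)
        Xte_sel = Xte_z.select_columns(selected)

        y_train = [usable[i] for i in train_ids]
        y_test = [usable[i] for i in split.test_ids]

        grid_results: dict[str, GridSearchResult] = {}
        for fam in self.families:
            grid_results[fam] = grid_search_cv(
                Xtr_sel, y_train, self.grids[fam], self.cv_folds, seed
            )
        best_family = max(
            self.families, key=lambda f: grid_results[f].best_mean_accuracy
        )
        best_params = grid_results[best_family].best_candidate

        estimator = train_estimator(best_family, best_params, Xtr_sel, y_train,
                                    seed=seed)
        knn = estimator.inner if best_family == "knn" else None

        ad = ad_fit(Xtr_sel, Z=self.ad_Z)

        # held-out evaluation
        classes = [ToxClass.LOW, ToxClass.HIGH]
        pred_codes = estimator.predict(Xte_sel)
        y_pred = [classes[int(c)] for c in pred_codes]
        cm = confusion(y_test, y_pred, self.positive_class)
        test_metrics = metrics(cm)

        predictions: list[PredictionRecord] = []
        for i, qid in enumerate(split.test_ids):
            x = Xte_sel.values[i]
            reliable, _ = ad_check(ad, x)
            if knn is not None:
                rec = knn_predict(knn, x, query_id=qid)
                rec.ad_reliable = reliable
            else:
                rec = PredictionRecord(qid, y_pred[i], float(pred_codes[i]), [],
                                       ad_reliable=reliable)
            predictions.append(rec)

        return ReadAcrossResults(
            model=self,
            seed=seed,
            split=split,
            column_filter=filt,
            duplicate_report=dup_report,
            normalizer=norm,
            boruta_result=boruta_res,
            selected_features=selected,
            grid_results=grid_results,
            best_family=best_family,
            best_params=best_params,
            estimator=estimator,
            knn=knn,
            ad=ad,
            train_ids=train_ids,
            X_train_selected=Xtr_sel,
            X_test_selected=Xte_sel,
            y_train=y_train,
            y_test=y_test,
            test_confusion=cm,
            test_metrics=test_metrics,
            predictions=predictions,
        )


@dataclass
class ReadAcrossResults:
    """Fitted pipeline artefacts, held-out metrics and reporting methods."""

    model: ReadAcrossModel
    seed: int
    split: SplitResult
    column_filter: ColumnFilterResult
    duplicate_report: DuplicateReport
    normalizer: Normalizer
    boruta_result: BorutaResult
    selected_features: list[str]
    grid_results: dict[str, GridSearchResult]
    best_family: str
    best_params: dict
    estimator: FittedEstimator
    knn: KNNModel | None
    ad: ADModel
    train_ids: list[str]
    X_train_selected: DescriptorMatrix
    X_test_selected: DescriptorMatrix
    y_train: list[ToxClass]
    y_test: list[ToxClass]
    test_confusion: ConfusionMatrix
    test_metrics: MetricsReport
    predictions: list[PredictionRecord]

    @property
    def cv_accuracy(self) -> float:
        """Mean stratified-CV accuracy of the winning candidate."""
        return self.grid_results[self.best_family].best_mean_accuracy

    # ------------------------------------------------------------------ #

    def _transform_queries(self, descriptors) -> DescriptorMatrix:
        if isinstance(descriptors, pd.DataFrame):
            descriptors = DescriptorMatrix(descriptors)
        return _apply_selected(self.normalizer, self.selected_features,
                               descriptors)

    def predict(self, descriptors) -> list[PredictionRecord]:
        """Classify new compounds from their raw descriptor rows.

        Applies the train-fitted z-score parameters and feature selection,
        then the fitted estimator; each record carries the neighbour group
        (kNN only) and the applicability-domain flag.  Out-of-domain
        queries are returned flagged, never suppressed.
        """
        z = self._transform_queries(descriptors)
        out = []
        classes = [ToxClass.LOW, ToxClass.HIGH]
        for i, qid in enumerate(z.row_ids):
            x = z.values[i]
            reliable, _ = ad_check(self.ad, x)
            if self.knn is not None:
                rec = knn_predict(self.knn, x, query_id=qid)
                rec.ad_reliable = reliable
            else:
                code = int(self.estimator.predict(x[None, :])[0])
                rec = PredictionRecord(qid, classes[code], float(code), [],
                                       ad_reliable=reliable)
            out.append(rec)
        return out

    def predictions_frame(
        self, predictions: Sequence[PredictionRecord] | None = None
    ) -> pd.DataFrame:
        """Tabular prediction report (class, vote, neighbours, AD flag)."""
        preds = self.predictions if predictions is None else list(predictions)
        rows = []
        for p in preds:
            row = {
                "id": p.query_id,
                "predicted_class": str(p.predicted_class),
                "vote_fraction_high": p.vote_fraction_high,
                "reliable": p.ad_reliable,
            }
            for j, (nid, d) in enumerate(p.neighbours, start=1):
                row[f"neighbour_{j}"] = nid
                row[f"distance_{j}"] = round(d, 3)
            rows.append(row)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ #

    def cross_validate(self, n_folds: int = 10, seed: int | None = None) -> CVReport:
        """Stratified k-fold CV of the winning candidate on the training set."""
        return kfold_cv(
            self.X_train_selected, self.y_train, self.best_family,
            self.best_params, n_folds=n_folds,
            seed=self.seed if seed is None else seed,
            positive_class=self.model.positive_class,
        )

    def y_randomize(self, n_iter: int = 10, seed: int | None = None) -> YRandReport:
        """Label-permutation robustness check on the untouched test set."""
        return y_randomization(
            self.X_train_selected, self.y_train,
            self.X_test_selected, self.y_test,
            self.best_family, self.best_params, n_iter=n_iter,
            seed=self.seed if seed is None else seed,
            positive_class=self.model.positive_class,
        )

    # ------------------------------------------------------------------ #

    def _predict_fraction_high(self, X: np.ndarray) -> np.ndarray:
        if self.knn is not None:
            return self.knn.vote_fraction(X)
        return self.estimator.predict(X).astype(float)

    def explain(
        self,
        descriptors=None,
        max_background: int = 100,
        seed: int | None = None,
    ) -> list[ShapleyExplanation]:
        """Exact Shapley attributions of the high-class vote fraction.

        Explains the held-out predictions by default, or any raw descriptor
        rows passed in.  The background is the selected, z-scored training
        matrix, subsampled to ``max_background`` rows under the seed.
        """
        if descriptors is None:
            z = self.X_test_selected
        else:
            z = self._transform_queries(descriptors)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        bg = self.X_train_selected.values
        if bg.shape[0] > max_background:
            bg = bg[rng.choice(bg.shape[0], max_background, replace=False)]
        out = []
        for i, qid in enumerate(z.row_ids):
            out.append(
                shapley_exact(
                    self._predict_fraction_high, z.values[i], bg,
                    feature_names=self.selected_features, query_id=qid,
                )
            )
        return out

    def read_across(self, query_id: str) -> ReadAcrossReport:
        """Similarity-group report for one held-out compound."""
        if self.knn is None:
            raise ValidationError(
                "read-across reporting requires the kNN model "
                f"(winner was {self.best_family})"
            )
        if query_id not in self.X_test_selected.row_ids:
            raise ValidationError(f"{query_id!r} is not a held-out compound")
        i = self.X_test_selected.row_ids.index(query_id)
        lookup = self.model.dataset.record_by_id()
        return read_across_report(
            self.knn, self.X_test_selected.values[i], self.ad, lookup,
            query_id=query_id, query_smiles=lookup[query_id].smiles,
        )

    # ------------------------------------------------------------------ #

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline and its metrics."""
        m = self.test_metrics
        gl = self.grid_results[self.best_family]
        lines = [
            "Read-across acute oral toxicity classifier",
            "=" * 58,
            f"compounds: {len(self.split.train_ids) + len(self.split.test_ids)}"
            f"  (train {len(self.split.train_ids)} / test {len(self.split.test_ids)},"
            f" stratified {1 - self.split.test_fraction:.0%}/{self.split.test_fraction:.0%},"
            f" seed {self.split.seed})",
            f"duplicate rows removed: {len(self.duplicate_report.removed_ids)}"
            f"  -> final training rows: {len(self.train_ids)}",
            f"columns: {len(self.column_filter.kept) + len(self.column_filter.dropped)}"
            f" -> {len(self.column_filter.kept)} after repeated-value filter"
            f" (> {self.model.max_repeat_fraction:.0%} identical dropped)",
            f"Boruta: {len(self.boruta_result.confirmed)} confirmed,"
            f" {len(self.boruta_result.tentative)} tentative,"
            f" {len(self.boruta_result.rejected)} rejected"
            f" in {self.boruta_result.n_iterations_run} iterations",
            f"selected features: {', '.join(self.selected_features)}",
            f"model: {self.best_family} {self.best_params}"
            f"  ({self.model.cv_folds}-fold CV accuracy"
            f" {gl.best_mean_accuracy:.3f})",
            f"applicability domain: thr = {self.ad.thr:.3f}"
            f" (d_bar {self.ad.d_bar:.3f}, sigma {self.ad.sigma:.3f},"
            f" Z {self.ad.Z})",
            "-" * 58,
            f"held-out metrics (positive class = "
            f"{self.model.positive_class}):",
            f"  ACC {m.ACC:.3f}  PRE {m.PRE:.3f}  SEN {m.SEN:.3f}"
            f"  SPE {m.SPE:.3f}  F1 {m.F1:.3f}  MCC {m.MCC:.3f}",
            f"  confusion: TP {self.test_confusion.TP}"
            f"  FP {self.test_confusion.FP}"
            f"  FN {self.test_confusion.FN}"
            f"  TN {self.test_confusion.TN}",
            f"  reliable predictions: "
            f"{sum(1 for p in self.predictions if p.ad_reliable)}"
            f"/{len(self.predictions)}",
        ]
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Persist the fitted model as a directory of plain-text artefacts."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.normalizer.to_json(d / "normalizer.json")
        (d / "selected_features.txt").write_text(
            "\n".join(self.selected_features) + "\n"
        )
        self.X_train_selected.to_csv(d / "train_matrix.csv")
        pd.DataFrame(
            {"id": self.train_ids, "tox_class": [str(c) for c in self.y_train]}
        ).to_csv(d / "train_labels.csv", index=False)
        (d / "hyperparameters.yaml").write_text(
            yaml.safe_dump(
                {"family": self.best_family, "params": self.best_params,
                 "positive_class": str(self.model.positive_class),
                 "seed": self.seed},
                sort_keys=False,
            )
        )
        self.ad.to_json(d / "ad.json")
        self.grid_results[self.best_family].to_frame().to_csv(
            d / "grid_search.csv", index=False
        )
        self.boruta_result.to_csv(d / "boruta.csv")
        self.split.to_csv(d / "split.csv")


@dataclass
class SavedModel:
    """A fitted model reloaded from its plain-text artefact directory."""

    normalizer: Normalizer
    selected_features: list[str]
    family: str
    params: dict
    estimator: FittedEstimator
    knn: KNNModel | None
    ad: ADModel
    train_matrix: DescriptorMatrix
    train_labels: list[ToxClass]
    positive_class: ToxClass

    def _transform(self, descriptors) -> DescriptorMatrix:
        if isinstance(descriptors, pd.DataFrame):
            descriptors = DescriptorMatrix(descriptors)
        return _apply_selected(self.normalizer, self.selected_features,
                               descriptors)

    def predict(self, descriptors) -> list[PredictionRecord]:
        z = self._transform(descriptors)
        classes = [ToxClass.LOW, ToxClass.HIGH]
        out = []
        for i, qid in enumerate(z.row_ids):
            x = z.values[i]
            reliable, _ = ad_check(self.ad, x)
            if self.knn is not None:
                rec = knn_predict(self.knn, x, query_id=qid)
                rec.ad_reliable = reliable
            else:
                code = int(self.estimator.predict(x[None, :])[0])
                rec = PredictionRecord(qid, classes[code], float(code), [],
                                       ad_reliable=reliable)
            out.append(rec)
        return out

    def explain(self, descriptors, max_background: int = 100,
                seed: int = 0) -> list[ShapleyExplanation]:
        z = self._transform(descriptors)
        rng = np.random.default_rng(seed)
        bg = self.train_matrix.values
        if bg.shape[0] > max_background:
            bg = bg[rng.choice(bg.shape[0], max_background, replace=False)]
        if self.knn is not None:
            fn = self.knn.vote_fraction
        else:
            fn = lambda X: self.estimator.predict(X).astype(float)
        return [
            shapley_exact(fn, z.values[i], bg,
                          feature_names=self.selected_features, query_id=qid)
            for i, qid in enumerate(z.row_ids)
        ]


def load_model(directory: str | Path) -> SavedModel:
    """Reload a model persisted by :meth:`ReadAcrossResults.save`.

    The kNN family is rebuilt exactly from the stored training matrix and
    labels; other families are refit deterministically from the same
    artefacts with the stored hyperparameters and seed.
    """
    d = Path(directory)
    norm = Normalizer.from_json(d / "normalizer.json")
    features = [
        ln for ln in (d / "selected_features.txt").read_text().splitlines() if ln
    ]
    hp = yaml.safe_load((d / "hyperparameters.yaml").read_text())
    train_df = pd.read_csv(d / "train_matrix.csv", dtype={"id": str}).set_index("id")
    train = DescriptorMatrix(train_df.astype(float))
    lab_df = pd.read_csv(d / "train_labels.csv", dtype=str)
    labels = [ToxClass(v) for v in lab_df["tox_class"]]
    ad = ADModel.from_json(d / "ad.json")
    estimator = train_estimator(hp["family"], hp["params"], train, labels,
                                seed=int(hp.get("seed", 0)))
    return SavedModel(
        normalizer=norm,
        selected_features=features,
        family=hp["family"],
        params=hp["params"],
        estimator=estimator,
        knn=estimator.inner if hp["family"] == "knn" else None,
        ad=ad,
        train_matrix=train,
        train_labels=labels,
        positive_class=ToxClass(hp.get("positive_class", "low")),
    )
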