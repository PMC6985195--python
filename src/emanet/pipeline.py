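"""Per-person analysis pipeline and cohort assembly.

Orchestrates, for each person: endorsement screen -> complete cases ->
temporal basis -> embedded-node network (approach 1) -> LASSO/OLS
detrending -> residual network (approach 2) -> centrality and the
raw-vs-detrended comparison -> a written result bundle with a manifest
of content hashes.  All randomness (cross-validation folds) flows from
one master seed, so a rerun with identical input and configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import CentralityTable, compare_raw_vs_detrended, compute_centrality
from .detrend import (
    NOT_ENDORSED,
    DetrendConfig,
    DetrendResult,
    VarianceExplainedTable,
    detrend_person,
)
from .ema_data import (
    EmaDataset,
    EndorsementReport,
    InsufficientDataError,
    SymptomSchema,
    complete_cases,
    read_ema_csv,
    screen_endorsement,
)
from .network import NetworkConfig, NetworkEstimate, approach1_embedded_network, approach2_residual_network
from .temporal_basis import build_basis, standardize_basis

__all__ = ["RunConfig", "PersonResult", "run_person", "run_cohort"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    min_nonzero: int = 3
    min_sd: float = 0.1
    min_rows: int = 10
    cv_folds: int = 10
    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation: str = "pearson"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ebic_gamma <= 1.0:
            raise ValueError("ebic_gamma must be in [0, 1]")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.correlation!r}")
        if self.cv_folds < 2 or self.n_lambda < 2 or self.min_rows < 2:
            raise ValueError("degenerate configuration")

    @property
    def detrend(self) -> DetrendConfig:
        return DetrendConfig(cv_folds=self.cv_folds, seed=self.seed)

    @property
    def network(self) -> NetworkConfig:
        return NetworkConfig(
            ebic_gamma=self.ebic_gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            correlation=self.correlation,
        )


@dataclass
class PersonResult:
    person_id: str
    endorsement: EndorsementReport
    table_column: dict[str, float | str]
    detrend_results: list[DetrendResult] = field(default_factory=list)
    network_raw: NetworkEstimate | None = None  # approach 1, temporal nodes embedded
    network_detrended: NetworkEstimate | None = None  # approach 2, residuals
    centrality_raw: CentralityTable | None = None
    centrality_detrended: CentralityTable | None = None
    comparison: pd.DataFrame | None = None
    complete: bool = True
    errors: list[str] = field(default_factory=list)


def run_person(ds: EmaDataset, cfg: RunConfig = RunConfig()) -> PersonResult:
    """Run both analysis approaches for one person."""
    rep = screen_endorsement(ds, min_nonzero=cfg.min_nonzero, min_sd=cfg.min_sd)
    column: dict[str, float | str] = {s: NOT_ENDORSED for s in ds.symptoms}
    result = PersonResult(person_id=ds.person_id, endorsement=rep, table_column=column)
    endorsed = rep.endorsed
    if not endorsed:
        result.complete = False
        result.errors.append("screen: no endorsed symptoms")
        return result
    try:
        cc = complete_cases(ds, endorsed, min_rows=cfg.min_rows)
    except InsufficientDataError as exc:
        result.complete = False
        result.errors.append(f"complete_cases: {exc}")
        return result

    basis = standardize_basis(build_basis(cc.timestamps))

    try:
        result.network_raw = approach1_embedded_network(cc, basis, cfg.network)
        result.centrality_raw = compute_centrality(result.network_raw)
    except Exception as exc:
        result.complete = False
        result.errors.append(f"approach1: {exc}")

    try:
        detrended, col = detrend_person(cc, basis, cfg.detrend, all_symptoms=ds.symptoms)
        result.detrend_results = detrended
        result.table_column = col
        result.network_detrended = approach2_residual_network(detrended, cfg.network)
        result.centrality_detrended = compute_centrality(result.network_detrended)
    except Exception as exc:
        result.complete = False
        result.errors.append(f"approach2: {exc}")

    if result.centrality_raw is not None and result.centrality_detrended is not None:
        try:
            result.comparison = compare_raw_vs_detrended(
                result.centrality_raw, result.centrality_detrended
            )
        except ValueError as exc:
            result.errors.append(f"comparison: {exc}")
    return result


def run_cohort(
    datasets: list[EmaDataset] | list[str | Path],
    cfg: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
    schema: SymptomSchema | None = None,
) -> tuple[list[PersonResult], VarianceExplainedTable]:
    """Run the pipeline over a cohort, isolating per-person failures.

    ``datasets`` may be in-memory datasets or paths to long-format CSVs.
    Returns per-person results and the assembled variance-explained
    table; if ``out_dir`` is given each person's bundle plus the cohort
    table are written there with a manifest.
    """
    loaded: list[EmaDataset | str] = []
    for item in datasets:
        if isinstance(item, EmaDataset):
            loaded.append(item)
        else:
            try:
                loaded.extend(read_ema_csv(item, schema).values())
            except Exception as exc:
                loaded.append(f"{item}: {exc}")

    results: list[PersonResult] = []
    columns: dict[str, dict[str, float | str]] = {}
    symptoms: list[str] | None = None
    for item in loaded:
        if isinstance(item, str):  # unreadable file: record, keep going
            results.append(
                PersonResult(
                    person_id=item.split(":")[0],
                    endorsement=EndorsementReport(person_id="?"),
                    table_column={},
                    complete=False,
                    errors=[f"read: {item}"],
                )
            )
            continue
        res = run_person(item, cfg)
        results.append(res)
        if res.table_column:
            columns[res.person_id] = res.table_column
            if symptoms is None:
                symptoms = list(item.symptoms)
    table = VarianceExplainedTable.from_columns(columns, symptoms=symptoms)
    if out_dir is not None:
        write_cohort_bundle(results, table, out_dir)
    return results, table


# ---------------------------------------------------------------------------
# bundle serialization


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonify(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, float) and x != x:
        return None
    return x


def _network_json(net: NetworkEstimate) -> dict:
    return _jsonify(
        {
            "nodes": list(net.nodes),
            "kinds": list(net.kinds),
            "W": net.W,
            "selected_lambda": None if net.selected_lambda != net.selected_lambda else net.selected_lambda,
            "lambda_path": [float(net.lambda_path[0]), float(net.lambda_path[-1]), len(net.lambda_path)]
            if len(net.lambda_path)
            else [],
            "ebic_gamma": net.ebic_gamma,
            "n_obs": net.n_obs,
            "n_edges": net.n_edges,
            "uninterpretable": net.uninterpretable,
            "notes": list(net.notes),
        }
    )


def write_person_bundle(res: PersonResult, out_dir: str | Path) -> dict[str, str]:
    """Write one person's artifacts; returns {relative path: sha256}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def put(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        files[name] = hashlib.sha256(text.encode()).hexdigest()

    put(
        "endorsement.csv",
        res.endorsement.to_frame().to_csv(index=False, float_format="%.6g"),
    )
    put(
        "detrend.json",
        json.dumps(_jsonify([r.to_dict() for r in res.detrend_results]), indent=1),
    )
    for tag, net, cent in (
        ("raw", res.network_raw, res.centrality_raw),
        ("detrended", res.network_detrended, res.centrality_detrended),
    ):
        if net is not None:
            put(f"network_{tag}.json", json.dumps(_network_json(net), indent=1))
            put(
                f"edges_{tag}.csv",
                net.edge_frame().to_csv(index=False, float_format="%.6g"),
            )
        if cent is not None:
            put(
                f"centrality_{tag}.csv",
                cent.to_frame().to_csv(index=False, float_format="%.6g"),
            )
    if res.comparison is not None:
        put(
            "comparison.csv",
            res.comparison.to_csv(index=False, float_format="%.6g"),
        )
        put(
            "comparison_meta.json",
            json.dumps(_jsonify(dict(res.comparison.attrs)), indent=1),
        )
    put(
        "status.json",
        json.dumps({"person_id": res.person_id, "complete": res.complete, "errors": res.errors}, indent=1),
    )
    return files


def write_cohort_bundle(
    results: list[PersonResult],
    table: VarianceExplainedTable,
    out_dir: str | Path,
) -> Path:
    """Write per-person bundles, the cohort table and a hash manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for res in results:
        files = write_person_bundle(res, out / res.person_id)
        manifest.update({f"{res.person_id}/{k}": v for k, v in files.items()})
    table_text = _table_csv_text(table)
    (out / "variance_explained.csv").write_text(table_text)
    manifest["variance_explained.csv"] = hashlib.sha256(table_text.encode()).hexdigest()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def _table_csv_text(table: VarianceExplainedTable) -> str:
    rendered = table.render()
    rendered.index.name = "symptom"
    return rendered.to_csv()
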