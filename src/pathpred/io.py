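"""Dataset readers/writers and the pathway-database importer.

On-disk dataset layout (UTF-8, tab-separated, header row):

* ``entities.tsv``      — id, name
* ``reactions.tsv``     — id, name
* ``attributes.tsv``    — id, name
* ``memberships.tsv``   — reaction_id, entity_id, role in {input, output}
* ``assignments.tsv``   — entity_id, attribute_id

``dataset.json`` mirrors the same five arrays in one document.  Writing is
deterministic (record/declaration order), so writing twice yields byte-
identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .network import INPUT, OUTPUT, PathwayNetwork, build_network

logger = logging.getLogger("pathpred")

TSV_FILES = ("entities.tsv", "reactions.tsv", "attributes.tsv",
             "memberships.tsv", "assignments.tsv")


class DatasetFormatError(ValueError):
    pass


def _read_tsv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise DatasetFormatError(f"missing dataset file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(columns):
        raise DatasetFormatError(
            f"{path}: expected columns {list(columns)}, got {list(df.columns)}")
    for i, row in enumerate(df.itertuples(index=False)):
        if any(val == "" for val in row):
            raise DatasetFormatError(f"{path}: malformed row at line {i + 2}")
    return df


def _normalize_role(token: str, path: Path, line: int) -> str:
    role = token.strip().lower()
    if role not in (INPUT, OUTPUT):
        raise DatasetFormatError(
            f"{path}: unknown role {token!r} at line {line}")
    return role


def read_dataset(directory: str | Path) -> PathwayNetwork:
    """Load a five-file TSV dataset (or its ``dataset.json`` mirror)."""
    directory = Path(directory)
    json_path = directory / "dataset.json"
    if json_path.exists() and not (directory / "entities.tsv").exists():
        return read_dataset_json(json_path)
    ents = _read_tsv(directory / "entities.tsv", ("id", "name"))
    rxns = _read_tsv(directory / "reactions.tsv", ("id", "name"))
    attrs = _read_tsv(directory / "attributes.tsv", ("id", "name"))
    mem_path = directory / "memberships.tsv"
    mems = _read_tsv(mem_path, ("reaction_id", "entity_id", "role"))
    asns = _read_tsv(directory / "assignments.tsv", ("entity_id", "attribute_id"))
    memberships = [
        (row.entity_id, row.reaction_id,
         _normalize_role(row.role, mem_path, i + 2))
        for i, row in enumerate(mems.itertuples(index=False))
    ]
    assignments = [(row.entity_id, row.attribute_id)
                   for row in asns.itertuples(index=False)]
    try:
        return build_network(
            list(ents.itertuples(index=False, name=None)),
            list(rxns.itertuples(index=False, name=None)),
            list(attrs.itertuples(index=False, name=None)),
            memberships, assignments)
    except ValueError as exc:
        raise DatasetFormatError(f"{directory}: {exc}") from exc


def read_dataset_json(path: str | Path) -> PathwayNetwork:
    doc = json.loads(Path(path).read_text())
    return build_network(
        [(r["id"], r["name"]) for r in doc["entities"]],
        [(r["id"], r["name"]) for r in doc["reactions"]],
        [(r["id"], r["name"]) for r in doc["attributes"]],
        [(m["entity_id"], m["reaction_id"], m["role"])
         for m in doc["memberships"]],
        [(a["entity_id"], a["attribute_id"]) for a in doc["assignments"]],
    )


def write_dataset(network: PathwayNetwork, directory: str | Path,
                  json_mirror: bool = False) -> list[Path]:
    """Write the five TSVs (and optionally ``dataset.json``); idempotent."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ents, rxns, attrs, member_ids, assign_ids = network.decompose()
    frames = {
        "entities.tsv": pd.DataFrame(ents, columns=["id", "name"]),
        "reactions.tsv": pd.DataFrame(rxns, columns=["id", "name"]),
        "attributes.tsv": pd.DataFrame(attrs, columns=["id", "name"]),
        "memberships.tsv": pd.DataFrame(
            [(e, v, r) for (v, e, r) in member_ids],
            columns=["reaction_id", "entity_id", "role"]),
        "assignments.tsv": pd.DataFrame(
            assign_ids, columns=["entity_id", "attribute_id"]),
    }
    written = []
    for fname, df in frames.items():
        path = directory / fname
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    if json_mirror:
        path = directory / "dataset.json"
        doc = {
            "entities": [{"id": i, "name": n} for (i, n) in ents],
            "reactions": [{"id": i, "name": n} for (i, n) in rxns],
            "attributes": [{"id": i, "name": n} for (i, n) in attrs],
            "memberships": [
                {"reaction_id": e, "entity_id": v, "role": r}
                for (v, e, r) in member_ids],
            "assignments": [
                {"entity_id": v, "attribute_id": f} for (v, f) in assign_ids],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        written.append(path)
    return written


def import_pathway_export(relations_file: str | Path,
                          components_file: str | Path,
                          role_map: dict[str, str] | None = None
                          ) -> PathwayNetwork:
    """Build a network from a generic two-file pathway-database export.

    ``relations_file``: TSV with columns (reaction_id, entity_id, role);
    ``components_file``: TSV with columns (entity_id, component_id) — the
    components become the entities' attributes.  Duplicated rows are
    dropped; role tokens outside {input, output} are mapped through
    ``role_map`` (default: everything else, e.g. ``catalyst``, counts as an
    input) with a logged count.  Unparseable rows are skipped with a
    warning; zero usable relation rows is an error.
    """
    role_map = {k.lower(): v for k, v in (role_map or {}).items()}
    relations, skipped = [], 0
    for line_no, parts in _iter_rows(relations_file, 3):
        if parts is None:
            skipped += 1
            continue
        rid, vid, role = parts
        role = role.strip().lower()
        if role not in (INPUT, OUTPUT):
            mapped = role_map.get(role, INPUT)
            logger.info("row %d: role %r mapped to %r", line_no, role, mapped)
            role = mapped
        relations.append((rid, vid, role))
    components = []
    for line_no, parts in _iter_rows(components_file, 2):
        if parts is None:
            skipped += 1
            continue
        components.append(tuple(parts))
    if skipped:
        logger.warning("importer skipped %d unparseable rows", skipped)
    relations = list(dict.fromkeys(relations))
    components = list(dict.fromkeys(components))
    if not relations:
        raise DatasetFormatError("no usable relation rows")

    entity_ids = list(dict.fromkeys(
        [v for (_, v, _) in relations] + [v for (v, _) in components]))
    reaction_ids = list(dict.fromkeys(r for (r, _, _) in relations))
    attribute_ids = list(dict.fromkeys(c for (_, c) in components))
    network = build_network(
        entity_ids, reaction_ids, attribute_ids,
        [(v, r, role) for (r, v, role) in relations],
        components)
    logger.info(
        "imported network: %d reactions, %d entities, %d attributes, "
        "%d reaction-entity relationships, %d entity-attribute relationships",
        network.n_reactions, network.n_entities, network.n_attributes,
        len(relations), len(components))
    return network


def _iter_rows(path: str | Path, n_cols: int):
    """Yield (line_no, fields | None) for each data row of a TSV; a header
    row is detected and skipped when its fields are not data-like."""
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        parts = line.split("\t")
        if i == 0 and any(h in parts[0].lower()
                          for h in ("id", "reaction", "entity")):
            continue
        if len(parts) != n_cols or any(not p.strip() for p in parts):
            yield i + 1, None
        else:
            yield i + 1, [p.strip() for p in parts]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path: str | Path) -> Path:
    """Serialise a fitted estimator (without its training network) to .npz."""
    from . import models as M
    from .estimators import AttributePredictor, LinkPredictor

    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta = {"class": type(model).__name__, "params": model.get_params()}
    p = model.params_
    if isinstance(p, M.MFParams):
        meta["param_kind"] = "mf"
        arrays.update(mu=np.array(p.mu), b_z=p.b_z, b_r=p.b_r, Z=p.Z, R=p.R)
    else:
        meta["param_kind"] = "layers"
        meta["layer_meta"] = {"kind": p.kind, "n_layers": p.n_layers,
                              "activation": p.activation}
        arrays["rho"] = p.rho
        for l, t in enumerate(p.theta_per_layer):
            arrays[f"theta{l}"] = t
    if isinstance(model, AttributePredictor):
        arrays["classifier_weight"] = model.classifier_weight_
        arrays["classifier_bias"] = model.classifier_bias_
    arrays["embeddings"] = model.embeddings_
    arrays["loss_history"] = np.asarray(model.loss_history_)
    np.savez(path, _meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path, network: PathwayNetwork):
    """Restore an estimator; forward outputs are bit-identical to the saved
    model's.  The training network must be supplied (checkpoints store
    parameters, not data)."""
    from . import models as M
    from .estimators import AttributePredictor, LinkPredictor

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        cls = {"LinkPredictor": LinkPredictor,
               "AttributePredictor": AttributePredictor}[meta["class"]]
        model = cls(**meta["params"])
        if meta["param_kind"] == "mf":
            params = M.MFParams(mu=float(data["mu"]), b_z=data["b_z"],
                                b_r=data["b_r"], Z=data["Z"], R=data["R"])
        else:
            lm = meta["layer_meta"]
            thetas = [data[f"theta{l}"] for l in range(lm["n_layers"])]
            params = M.LayerParams(kind=lm["kind"], theta_per_layer=thetas,
                                   rho=data["rho"], n_layers=lm["n_layers"],
                                   activation=lm["activation"])
        model.params_ = params
        model.network_ = network
        model.loss_history_ = data["loss_history"].tolist()
        if meta["class"] == "AttributePredictor":
            model.classifier_weight_ = data["classifier_weight"]
            model.classifier_bias_ = data["classifier_bias"]
            model._masked_network_ = network
        model.embeddings_ = data["embeddings"]
    return model
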