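"""The heterogeneous Adverse Event Report (AER) graph.

Nodes are patients, diseases, and drugs; directed edges link a patient
to each reported disease (``has_disease``) and each taken drug
(``takes``), with exact reverse types (``disease_of``, ``taken_by``) so
messages flow both ways. Patient node features are a bag-of-words
multi-hot over the disease and drug vocabularies, optionally followed by
a 9-entry demographic block; disease and drug features are one-hot
(identity).

ADRs are deliberately NOT nodes: the graph is built from training
reports only, and the ADR sets of training patients enter solely as the
label matrix ``Y``. Including patient-ADR edges would leak labels into
the representations of neighboring patients and break the inductive
evaluation, where new patients are attached by their diseases and
candidate drugs alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import AdverseEventReport, Vocabulary

__all__ = ["AERGraph", "FeatureConfig", "EDGE_TYPES", "build_graph",
           "patient_features", "attach_patients", "serialize_graph",
           "deserialize_graph"]

logger = logging.getLogger(__name__)

#: directed edge types as meta-relations: name -> (source type, target type)
EDGE_TYPES: dict[str, tuple[str, str]] = {
    "has_disease": ("patient", "disease"),
    "disease_of": ("disease", "patient"),
    "takes": ("patient", "drug"),
    "taken_by": ("drug", "patient"),
}
NODE_TYPES = ("patient", "disease", "drug")
DEMOGRAPHIC_WIDTH = 10
ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class FeatureConfig:
    """Layout of the patient feature vector.

    ``[disease multi-hot | drug multi-hot | demographics]`` where the
    demographic block (present iff ``include_demographics``) is
    ``[age/age_scale, sex one-hot(2), weight/weight_scale (0 if missing),
    weight-missing flag, qualification one-hot(5)]`` — 10 entries.
    Demographics default on: the perturbation experiments require gender
    and age to be model inputs.
    """

    include_demographics: bool = True
    age_scale: float = 100.0
    weight_scale: float = 100.0

    def patient_width(self, vocab: Vocabulary) -> int:
        return (vocab.n_diseases + vocab.n_drugs
                + (DEMOGRAPHIC_WIDTH if self.include_demographics else 0))


@dataclass
class AERGraph:
    """Typed node/edge store with features and training labels.

    Patients ``[0, n_train_patients)`` are training patients and own the
    rows of ``Y``; any further patients were attached inductively and
    carry no label information.
    """

    vocab: Vocabulary
    feature_config: FeatureConfig
    patient_ids: list[str]
    edges: dict[str, np.ndarray]        # name -> (2, E) int array [src; dst]
    x_patient: np.ndarray               # (n_patients, F_P)
    y: np.ndarray                       # (n_train_patients, n_adrs) binary
    n_train_patients: int = field(default=-1)

    def __post_init__(self):
        if self.n_train_patients == -1:
            self.n_train_patients = len(self.patient_ids)
        self.validate()

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def n_nodes(self, node_type: str) -> int:
        return {"patient": self.n_patients,
                "disease": self.vocab.n_diseases,
                "drug": self.vocab.n_drugs}[node_type]

    def node_features(self, node_type: str) -> np.ndarray:
        if node_type == "patient":
            return self.x_patient
        return np.eye(self.n_nodes(node_type))

    def validate(self) -> None:
        if set(self.edges) != set(EDGE_TYPES):
            raise ValueError(f"edge types must be exactly {sorted(EDGE_TYPES)}")
        for name, (src_t, dst_t) in EDGE_TYPES.items():
            e = self.edges[name]
            if e.ndim != 2 or e.shape[0] != 2:
                raise ValueError(f"edge array {name} must have shape (2, E)")
            if e.size and (e[0].min() < 0 or e[0].max() >= self.n_nodes(src_t)
                           or e[1].min() < 0 or e[1].max() >= self.n_nodes(dst_t)):
                raise ValueError(f"dangling endpoint in edge type {name}")
        def canon(e):
            return e[:, np.lexsort((e[1], e[0]))] if e.size else e
        for fwd, rev in [("has_disease", "disease_of"), ("takes", "taken_by")]:
            if not np.array_equal(canon(self.edges[fwd]),
                                  canon(self.edges[rev][::-1])):
                raise ValueError(f"{rev} is not the transpose of {fwd}")
        if self.x_patient.shape != (self.n_patients,
                                    self.feature_config.patient_width(self.vocab)):
            raise ValueError("patient feature matrix has the wrong shape")
        if self.y.shape != (self.n_train_patients, self.vocab.n_adrs):
            raise ValueError("label matrix has the wrong shape")
        if self.y.size and not (self.y.sum(axis=1) >= 1).all():
            raise ValueError("every training patient must have >= 1 ADR label")


def patient_features(report: AdverseEventReport, vocab: Vocabulary,
                     feature_config: FeatureConfig = FeatureConfig(),
                     inductive: bool = False) -> np.ndarray:
    """Bag-of-words feature vector for one patient.

    Unknown disease/drug IDs raise in training mode; in inductive mode
    they are dropped with a warning (the vocabulary is frozen at
    training time).
    """
    x = np.zeros(feature_config.patient_width(vocab))
    for ids, index, offset in [(report.diseases, vocab.disease_index, 0),
                               (report.drugs, vocab.drug_index, vocab.n_diseases)]:
        for item in sorted(ids):
            if item in index:
                x[offset + index[item]] = 1.0
            elif inductive:
                logger.warning("report %s: ID %s unseen in training, dropped",
                               report.report_id, item)
            else:
                raise KeyError(f"report {report.report_id}: unknown ID {item}")
    if feature_config.include_demographics:
        if not report.has_demographics:
            raise ValueError(f"report {report.report_id}: demographics required")
        o = vocab.n_diseases + vocab.n_drugs
        x[o] = report.age / feature_config.age_scale
        x[o + report.sex] = 1.0               # o+1 male, o+2 female
        if report.weight is not None:
            x[o + 3] = report.weight / feature_config.weight_scale
        else:
            x[o + 4] = 1.0                    # missing-weight flag
        x[o + 4 + report.qualification] = 1.0  # o+5 .. o+9
    return x


def _edges_for(reports, vocab: Vocabulary, patient_offset: int,
               inductive: bool) -> dict[str, list[list[int]]]:
    pairs = {name: [] for name in EDGE_TYPES}
    for i, r in enumerate(reports):
        p = patient_offset + i
        for d in sorted(r.diseases):
            if d in vocab.disease_index:
                j = vocab.disease_index[d]
                pairs["has_disease"].append([p, j])
                pairs["disease_of"].append([j, p])
            elif not inductive:
                raise KeyError(f"report {r.report_id}: unknown disease {d}")
            else:
                logger.warning("report %s: disease %s unseen, no edge",
                               r.report_id, d)
        for m in sorted(r.drugs):
            if m in vocab.drug_index:
                j = vocab.drug_index[m]
                pairs["takes"].append([p, j])
                pairs["taken_by"].append([j, p])
            elif not inductive:
                raise KeyError(f"report {r.report_id}: unknown drug {m}")
            else:
                logger.warning("report %s: drug %s unseen, no edge",
                               r.report_id, m)
    return pairs


def _as_edge_arrays(pairs: dict[str, list[list[int]]]) -> dict[str, np.ndarray]:
    return {name: (np.array(p, dtype=np.intp).T if p
                   else np.empty((2, 0), dtype=np.intp))
            for name, p in pairs.items()}


def build_graph(train_reports, vocab: Vocabulary,
                feature_config: FeatureConfig = FeatureConfig()) -> AERGraph:
    """Build the AER graph from training reports only."""
    train_reports = list(train_reports)
    if not train_reports:
        raise ValueError("cannot build a graph from zero training reports")
    x = np.stack([patient_features(r, vocab, feature_config)
                  for r in train_reports])
    y = np.zeros((len(train_reports), vocab.n_adrs))
    for i, r in enumerate(train_reports):
        for s in r.adrs:
            if s not in vocab.adr_index:
                raise KeyError(f"report {r.report_id}: unknown ADR {s}")
            y[i, vocab.adr_index[s]] = 1.0
    edges = _as_edge_arrays(_edges_for(train_reports, vocab, 0, inductive=False))
    return AERGraph(vocab=vocab, feature_config=feature_config,
                    patient_ids=[r.report_id for r in train_reports],
                    edges=edges, x_patient=x, y=y)


def attach_patients(graph: AERGraph, new_reports) -> AERGraph:
    """Attach new patients inductively; pure function, original unchanged.

    New patients get ``has_disease``/``takes`` edges (plus reverses) and
    features only — no label rows; their ADR sets never enter the graph.
    Entities unseen in training are dropped with a warning.
    """
    new_reports = list(new_reports)
    existing = set(graph.patient_ids)
    for r in new_reports:
        if r.report_id in existing:
            raise ValueError(f"report ID {r.report_id} already in the graph")
    if not new_reports:
        return AERGraph(vocab=graph.vocab, feature_config=graph.feature_config,
                        patient_ids=list(graph.patient_ids),
                        edges={k: v.copy() for k, v in graph.edges.items()},
                        x_patient=graph.x_patient.copy(), y=graph.y.copy(),
                        n_train_patients=graph.n_train_patients)
    new_pairs = _edges_for(new_reports, graph.vocab, graph.n_patients,
                           inductive=True)
    edges = {name: np.concatenate(
                 [graph.edges[name]] + ([np.array(p, dtype=np.intp).T]
                                        if (p := new_pairs[name]) else []),
                 axis=1)
             for name in EDGE_TYPES}
    x_new = np.stack([patient_features(r, graph.vocab, graph.feature_config,
                                       inductive=True) for r in new_reports])
    return AERGraph(vocab=graph.vocab, feature_config=graph.feature_config,
                    patient_ids=graph.patient_ids + [r.report_id
                                                     for r in new_reports],
                    edges=edges,
                    x_patient=np.concatenate([graph.x_patient, x_new]),
                    y=graph.y.copy(), n_train_patients=graph.n_train_patients)


def serialize_graph(graph: AERGraph, path) -> None:
    """Write the graph archive: TSV node/edge lists, dense feature and
    label matrices, and a versioned meta.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "nodes_patient.tsv", "w") as fh:
        fh.write("node_id\treport_id\n")
        for i, rid in enumerate(graph.patient_ids):
            fh.write(f"{i}\t{rid}\n")
    for nt, ids in [("disease", graph.vocab.diseases),
                    ("drug", graph.vocab.drugs), ("adr", graph.vocab.adrs)]:
        with open(path / f"nodes_{nt}.tsv", "w") as fh:
            fh.write("node_id\tentity_id\n")
            for i, eid in enumerate(ids):
                fh.write(f"{i}\t{eid}\n")
    for name, e in graph.edges.items():
        np.savetxt(path / f"edges_{name}.tsv", e.T, fmt="%d", delimiter="\t",
                   header="src\tdst", comments="")
    np.save(path / "features_patient.npy", graph.x_patient)
    np.save(path / "labels.npy", graph.y)
    meta = {
        "version": ARCHIVE_VERSION,
        "n_train_patients": int(graph.n_train_patients),
        "feature_config": {
            "include_demographics": graph.feature_config.include_demographics,
            "age_scale": float(graph.feature_config.age_scale),
            "weight_scale": float(graph.feature_config.weight_scale),
        },
    }
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def deserialize_graph(path) -> AERGraph:
    path = Path(path)
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    if meta.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported graph archive version {meta.get('version')}")

    def read_ids(name):
        with open(path / f"nodes_{name}.tsv") as fh:
            next(fh)
            return [line.rstrip("\n").split("\t")[1] for line in fh if line.strip()]

    patient_ids = read_ids("patient")
    vocab = Vocabulary(
        {d: i for i, d in enumerate(read_ids("disease"))},
        {m: i for i, m in enumerate(read_ids("drug"))},
        {s: i for i, s in enumerate(read_ids("adr"))},
    )
    fc = FeatureConfig(**meta["feature_config"])
    edges = {}
    for name in EDGE_TYPES:
        e = np.loadtxt(path / f"edges_{name}.tsv", dtype=np.intp,
                       delimiter="\t", skiprows=1, ndmin=2)
        edges[name] = e.T if e.size else np.empty((2, 0), dtype=np.intp)
    return AERGraph(vocab=vocab, feature_config=fc, patient_ids=patient_ids,
                    edges=edges,
                    x_patient=np.load(path / "features_patient.npy"),
                    y=np.load(path / "labels.npy"),
                    n_train_patients=int(meta["n_train_patients"]))
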