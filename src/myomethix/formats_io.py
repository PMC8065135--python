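"""Readers, writers and in-memory types for every external format.

All matrices, manifests and sample sheets travel as TSV (first column =
feature id, header row = sample ids / field names); gene sets as GMT;
motifs as JASPAR PFM; promoters as FASTA.  Downstream modules consume
only the types defined here.

Methylation beta values are stored internally as fractions in [0, 1];
percent appears only at the report boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

GENE_REGIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")
ISLAND_REGIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GROUPS = ("NGT", "T2D")
STATES = ("myoblast", "myotube")
SEXES = ("male", "female")

BETA_TOLERANCE = 1e-9

SAMPLE_SHEET_COLUMNS = ["sample_id", "subject_id", "group", "state", "age", "bmi", "sex"]
MANIFEST_COLUMNS = ["probe_id", "chromosome", "nearest_gene", "gene_region", "island_region"]

DYNAMICS_REPORT_COLUMNS = [
    "probe_id", "chromosome", "gene", "gene_region", "island_region",
    "ngt_myoblast_mean", "ngt_myoblast_sd", "ngt_myotube_mean", "ngt_myotube_sd",
    "ngt_difference", "ngt_p", "ngt_q",
    "t2d_myoblast_mean", "t2d_myoblast_sd", "t2d_myotube_mean", "t2d_myotube_sd",
    "t2d_difference", "t2d_p", "t2d_q",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class SampleSheet:
    """Typed wrapper around the sample sheet table.

    Enforces unique sample ids, closed group/state/sex vocabularies and at
    most one sample per (subject, state).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        frame = frame[SAMPLE_SHEET_COLUMNS].reset_index(drop=True).copy()
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        for col, allowed in (("group", GROUPS), ("state", STATES), ("sex", SEXES)):
            bad = set(frame[col]) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} value(s): {sorted(bad)}")
        if frame.duplicated(subset=["subject_id", "state"]).any():
            raise ValidationError("a (subject_id, state) pair appears more than once")
        frame["age"] = frame["age"].astype(float)
        frame["bmi"] = frame["bmi"].astype(float)
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subset(self, group: str | None = None, state: str | None = None) -> pd.DataFrame:
        f = self.frame
        if group is not None:
            f = f[f["group"] == group]
        if state is not None:
            f = f[f["state"] == state]
        return f

    def paired_subjects(self, group: str) -> list[str]:
        """Subjects of ``group`` that have samples in both states."""
        f = self.subset(group=group)
        counts = f.groupby("subject_id")["state"].nunique()
        return sorted(counts[counts == 2].index)

    def sample_for(self, subject_id: str, state: str) -> str:
        f = self.frame
        row = f[(f["subject_id"] == subject_id) & (f["state"] == state)]
        if row.empty:
            raise ValidationError(f"no sample for subject {subject_id!r} state {state!r}")
        return str(row["sample_id"].iloc[0])

    def group_indicator(self, sample_ids) -> np.ndarray:
        lookup = dict(zip(self.frame["sample_id"], self.frame["group"]))
        return np.array([1.0 if lookup[s] == "T2D" else 0.0 for s in sample_ids])

    def covariates(self, sample_ids) -> pd.DataFrame:
        """age, bmi and sex indicator (female = 0) for the given samples."""
        f = self.frame.set_index("sample_id").loc[list(sample_ids)]
        return pd.DataFrame({
            "age": f["age"].to_numpy(float),
            "bmi": f["bmi"].to_numpy(float),
            "sex_male": (f["sex"] == "male").to_numpy(float),
        })

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSheet) and self.frame.equals(other.frame)


@dataclass(frozen=True, eq=False)
class FeatureMatrix:
    """Ordered feature x sample matrix with unique ids and finite values."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __eq__(self, other) -> bool:
        return (type(self) is type(other)
                and self.feature_ids == other.feature_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values))

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(i) for i in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value for feature {self.feature_ids[i]!r} "
                f"sample {self.sample_ids[j]!r}")

    # -- accessors ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame):
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))

    def subset_samples(self, sample_ids):
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return replace(self, sample_ids=tuple(sample_ids),
                       values=self.values[:, cols])

    def row(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(feature_id) from None
        return self.values[i]

    @property
    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}


class ExpressionMatrix(FeatureMatrix):
    """log2 normalised expression, genes or probes x samples."""


class BetaMatrix(FeatureMatrix):
    """Methylation fractions in [0, 1] (percent only at report boundary)."""

    def __post_init__(self):
        super().__post_init__()
        low = self.values < -BETA_TOLERANCE
        high = self.values > 1.0 + BETA_TOLERANCE
        if low.any() or high.any():
            i, j = np.argwhere(low | high)[0]
            raise ValidationError(
                f"beta value {self.values[i, j]} outside [0, 1] for probe "
                f"{self.feature_ids[i]!r} sample {self.sample_ids[j]!r}")


class ProbeManifest:
    """Probe annotation; a probe mapped to several genes has several rows."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        frame = frame[MANIFEST_COLUMNS].reset_index(drop=True).copy()
        frame["nearest_gene"] = frame["nearest_gene"].fillna("").astype(str)
        frame.loc[frame["nearest_gene"].isin(("nan", "None")), "nearest_gene"] = ""
        for col, allowed in (("gene_region", GENE_REGIONS),
                             ("island_region", ISLAND_REGIONS)):
            bad = set(frame[col]) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} value(s): {sorted(bad)}")
        if frame.duplicated().any():
            frame = frame.drop_duplicates().reset_index(drop=True)
        self.frame = frame

    @property
    def probe_ids(self) -> set[str]:
        return set(self.frame["probe_id"])

    def rows_for_genes(self, genes) -> pd.DataFrame:
        genes = set(genes)
        f = self.frame
        return f[f["nearest_gene"].isin(genes)]

    def annotation_for(self, probe_id: str) -> dict:
        f = self.frame
        rows = f[f["probe_id"] == probe_id]
        if rows.empty:
            return {"chromosome": "", "nearest_gene": "",
                    "gene_region": "intergenic", "island_region": "OpenSea"}
        r = rows.iloc[0]
        genes = [g for g in rows["nearest_gene"] if g]
        return {"chromosome": str(r["chromosome"]),
                "nearest_gene": "; ".join(dict.fromkeys(genes)),
                "gene_region": str(r["gene_region"]),
                "island_region": str(r["island_region"])}

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeManifest) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


class GeneSetCollection(dict):
    """Mapping of set name -> :class:`GeneSet` with unique names."""

    @classmethod
    def from_sets(cls, sets) -> "GeneSetCollection":
        coll = cls()
        for s in sets:
            if s.name in coll:
                raise ValidationError(f"duplicate gene set name {s.name!r}")
            coll[s.name] = s
        return coll


@dataclass(frozen=True)
class MotifModel:
    """Position frequency matrix with background and pseudocount.

    ``counts`` rows are A, C, G, T; columns are motif positions.
    """

    name: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", background)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValidationError("motif counts must be a 4 x L matrix, L >= 1")
        if np.any(counts < 0):
            raise ValidationError("motif counts must be non-negative")
        if np.any(counts.sum(axis=0) == 0):
            raise ValidationError("motif has an all-zero column")
        if background.shape != (4,) or np.any(background <= 0):
            raise ValidationError("background must be 4 positive frequencies")
        if abs(background.sum() - 1.0) > 1e-6:
            raise ValidationError("background frequencies must sum to 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))


@dataclass
class CohortBundle:
    """Matched expression + methylation cohort with shared sample sheet."""

    expression: ExpressionMatrix
    beta: BetaMatrix
    manifest: ProbeManifest
    samples: SampleSheet
    truth: object | None = None


# ---------------------------------------------------------------------------
# TSV matrices, sheets, manifests
# ---------------------------------------------------------------------------

def _header_lines(header: dict | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in header.items())


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError("file does not exist", str(path))
    try:
        kwargs.setdefault("float_precision", "round_trip")
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except Exception as exc:                      # noqa: BLE001 - re-raise typed
        raise FormatError(f"could not parse TSV: {exc}", str(path)) from exc


def read_matrix_tsv(path, kind=FeatureMatrix):
    frame = _read_tsv(path, index_col=0)
    try:
        return kind.from_frame(frame)
    except ValidationError as exc:
        raise FormatError(str(exc), str(path)) from exc


def write_matrix_tsv(matrix: FeatureMatrix, path, feature_label: str = "feature_id",
                     header: dict | None = None) -> None:
    path = Path(path)
    frame = matrix.to_frame()
    frame.index.name = feature_label
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        # %.17g guarantees a bit-identical write -> read round trip
        frame.to_csv(fh, sep="\t", float_format="%.17g")


def read_expression_tsv(path) -> ExpressionMatrix:
    return read_matrix_tsv(path, ExpressionMatrix)


def read_beta_tsv(path) -> BetaMatrix:
    return read_matrix_tsv(path, BetaMatrix)


def read_sample_sheet_tsv(path) -> SampleSheet:
    frame = _read_tsv(path, dtype={"sample_id": str, "subject_id": str})
    try:
        return SampleSheet(frame)
    except ValidationError as exc:
        raise FormatError(str(exc), str(path)) from exc


def write_sample_sheet_tsv(sheet: SampleSheet, path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        sheet.frame.to_csv(fh, sep="\t", index=False)


def read_manifest_tsv(path) -> ProbeManifest:
    frame = _read_tsv(path, dtype=str)
    try:
        return ProbeManifest(frame)
    except ValidationError as exc:
        raise FormatError(str(exc), str(path)) from exc


def write_manifest_tsv(manifest: ProbeManifest, path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        manifest.frame.to_csv(fh, sep="\t", index=False)


def read_cohort(expression_path, beta_path, manifest_path, sample_sheet_path) -> CohortBundle:
    """Load a full cohort, aligning matrix columns to sample sheet order.

    Probes present in the beta matrix but absent from the manifest are
    retained and classed intergenic / OpenSea.
    """
    samples = read_sample_sheet_tsv(sample_sheet_path)
    expression = read_expression_tsv(expression_path)
    beta = read_beta_tsv(beta_path)
    manifest = read_manifest_tsv(manifest_path)

    sheet_order = samples.sample_ids
    for matrix, path in ((expression, expression_path), (beta, beta_path)):
        extra = set(matrix.sample_ids) - set(sheet_order)
        if extra:
            raise FormatError(
                f"samples {sorted(extra)} not present in the sample sheet",
                str(path))
    expression = expression.subset_samples(
        [s for s in sheet_order if s in set(expression.sample_ids)])
    beta = beta.subset_samples(
        [s for s in sheet_order if s in set(beta.sample_ids)])

    missing = sorted(set(beta.feature_ids) - manifest.probe_ids)
    if missing:
        filler = pd.DataFrame({
            "probe_id": missing,
            "chromosome": "",
            "nearest_gene": "",
            "gene_region": "intergenic",
            "island_region": "OpenSea",
        })
        manifest = ProbeManifest(pd.concat([manifest.frame, filler], ignore_index=True))
    return CohortBundle(expression=expression, beta=beta, manifest=manifest,
                        samples=samples)


# ---------------------------------------------------------------------------
# GMT, JASPAR PFM, FASTA
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise FormatError("file does not exist", str(path))
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"line {lineno}: GMT rows need name, description "
                              "and at least one member", str(path))
        members = frozenset(m for m in parts[2:] if m)
        if not members:
            raise FormatError(f"line {lineno}: gene set {parts[0]!r} has no members",
                              str(path))
        sets.append(GeneSet(parts[0], parts[1], members))
    try:
        return GeneSetCollection.from_sets(sets)
    except ValidationError as exc:
        raise FormatError(str(exc), str(path)) from exc


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.values():
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_jaspar_pfm(path, background=None, pseudocount: float = 0.8) -> MotifModel:
    """Parse a single JASPAR-style PFM: '>name' then 4 labeled count rows."""
    path = Path(path)
    if not path.exists():
        raise FormatError("file does not exist", str(path))
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise FormatError("PFM must start with a '>' header line", str(path))
    name = lines[0][1:].strip().split()[0]
    rows: dict[str, list[float]] = {}
    for ln in lines[1:]:
        token = ln.split()[0].upper().rstrip(":")
        base = token if token in "ACGT" else None
        body = ln[len(ln.split()[0]):] if base else ln
        if base is None:
            raise FormatError(f"unlabeled PFM row: {ln!r}", str(path))
        body = body.replace("[", " ").replace("]", " ")
        try:
            rows[base] = [float(v) for v in body.split()]
        except ValueError as exc:
            raise FormatError(f"non-numeric PFM entry in row {base}", str(path)) from exc
    if sorted(rows) != ["A", "C", "G", "T"]:
        raise FormatError(f"PFM must have exactly 4 rows A, C, G, T "
                          f"(found {sorted(rows)})", str(path))
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError("PFM rows have unequal lengths", str(path))
    counts = np.array([rows[b] for b in "ACGT"], dtype=float)
    kwargs = {}
    if background is not None:
        kwargs["background"] = np.asarray(background, dtype=float)
    try:
        return MotifModel(name=name, counts=counts, pseudocount=pseudocount, **kwargs)
    except ValidationError as exc:
        raise FormatError(str(exc), str(path)) from exc


def write_jaspar_pfm(motif: MotifModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif.name}\n")
        for i, base in enumerate("ACGT"):
            row = " ".join(f"{v:g}" for v in motif.counts[i])
            fh.write(f"{base} [ {row} ]\n")


def read_fasta_promoters(path) -> dict[str, str]:
    """FASTA -> {gene symbol (first header token): sequence}."""
    path = Path(path)
    if not path.exists():
        raise FormatError("file does not exist", str(path))
    promoters: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = record.id.split()[0]
        if gene in promoters:
            raise FormatError(f"duplicate FASTA gene symbol {gene!r}", str(path))
        promoters[gene] = str(record.seq).upper()
    return promoters


def write_fasta_promoters(promoters: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="")
               for gene, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# dynamics report (percent-scale, one probe per row, both groups)
# ---------------------------------------------------------------------------

def parse_dynamics_report(path):
    """Parse a per-probe paired dynamics report into record pairs.

    The dialect matches the writer in :mod:`myomethix.diffmeth`: probe
    annotation columns followed by, per group, myoblast/myotube mean and
    SD, signed myotube-minus-myoblast difference, p and q — all percent
    fields stored as given.  Returns a list of
    :class:`myomethix.diffmeth.PairedDynamics`.
    """
    from .diffmeth import DynamicsRecord, PairedDynamics  # local: avoid cycle

    frame = _read_tsv(path, dtype=str)
    missing = [c for c in DYNAMICS_REPORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"dynamics report missing columns: {missing}", str(path))
    numeric_cols = DYNAMICS_REPORT_COLUMNS[5:]
    pairs = []
    for _, row in frame.iterrows():
        probe = str(row["probe_id"])
        values = {}
        for col in numeric_cols:
            raw = row[col]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                raise FormatError(f"missing value in column {col!r} for probe {probe}",
                                  str(path))
            try:
                values[col] = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric value {raw!r} in column {col!r} for probe {probe}",
                    str(path)) from exc
        annotation = {
            "chromosome": "" if pd.isna(row["chromosome"]) else str(row["chromosome"]),
            "gene": "" if pd.isna(row["gene"]) else str(row["gene"]),
            "gene_region": "" if pd.isna(row["gene_region"]) else str(row["gene_region"]),
            "island_region": "" if pd.isna(row["island_region"]) else str(row["island_region"]),
        }
        records = {}
        for group, prefix in (("NGT", "ngt"), ("T2D", "t2d")):
            records[group] = DynamicsRecord(
                probe_id=probe, group=group,
                mean_myoblast=values[f"{prefix}_myoblast_mean"],
                sd_myoblast=values[f"{prefix}_myoblast_sd"],
                mean_myotube=values[f"{prefix}_myotube_mean"],
                sd_myotube=values[f"{prefix}_myotube_sd"],
                difference=values[f"{prefix}_difference"],
                w=float("nan"), p=values[f"{prefix}_p"], q=values[f"{prefix}_q"],
                n=0, **annotation)
        pairs.append(PairedDynamics(probe_id=probe, ngt=records["NGT"],
                                    t2d=records["T2D"], **annotation))
    return pairs


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Flat key/value YAML config; every CLI flag can be overridden here."""
    path = Path(path)
    if not path.exists():
        raise FormatError("file does not exist", str(path))
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise FormatError("config must be a flat key/value mapping", str(path))
    for key, value in data.items():
        if isinstance(value, (dict, list)) and key != "term_queries":
            raise FormatError(f"config key {key!r} is not a flat value", str(path))
    return data
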