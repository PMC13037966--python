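"""Expression matrices and study designs.

The analysis operates on a genes x samples matrix of TPM values together with a
study design that assigns every sample to a (cell line, treatment) group, pairs
a control group with a treated group within each cell line ("treatment pair"),
and assigns each cell line a phenotype role: "A" for lines showing the
phenotype of interest (drug-responsive / effective) and "B" for reference lines
that do not (non-effective).

Missing cells are not permitted: upstream quantifiers emit 0 for unexpressed
genes, and the NA concept downstream is defined through all-zero expression,
not through missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

GroupKey = tuple[str, str]  # (cell_line, treatment)

ROLE_A = "A"
ROLE_B = "B"


class MatrixFormatError(ValueError):
    """Raised when an expression matrix violates its invariants."""


class DesignError(ValueError):
    """Raised when a study design is internally inconsistent."""


@dataclass
class ExpressionMatrix:
    """Non-negative TPM values, genes as rows, samples as columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        dup_genes = df.index[df.index.duplicated()].unique().tolist()
        if dup_genes:
            raise MatrixFormatError(f"duplicate gene id(s): {dup_genes}")
        dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise MatrixFormatError(f"duplicate sample id(s): {dup_samples}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise MatrixFormatError("expression values must be numeric")
        bad = np.argwhere(~np.isfinite(arr))
        if bad.size:
            i, j = bad[0]
            raise MatrixFormatError(
                f"non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise MatrixFormatError(
                f"negative TPM {arr[i, j]} at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write_tpm(self, path: str | Path) -> None:
        """Write as tab-separated text; round-trips to full printed precision."""
        # %.17g guarantees exact float round-trips through text
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_tpm_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated genes x samples TPM matrix.

    First column holds gene ids, header row holds sample ids. Duplicated ids,
    negative values and non-numeric cells are hard errors that name the
    offending location (pandas would silently mangle duplicate headers, so the
    header is checked verbatim first).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dup = sorted({s for s in samples if samples.count(s) > 1})
    if dup:
        raise MatrixFormatError(f"duplicate sample id(s) in header: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise MatrixFormatError(
            f"non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise MatrixFormatError(
            f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}; "
            "unexpressed genes must be encoded as 0"
        )
    # to_numeric can be one ulp off; astype uses correctly-rounded strtod
    return ExpressionMatrix(df.astype(float))


@dataclass(frozen=True)
class TreatmentPair:
    """A (control, treated) pair of groups within one cell line."""

    cell_line: str
    control: str
    treated: str

    @property
    def control_key(self) -> GroupKey:
        return (self.cell_line, self.control)

    @property
    def treated_key(self) -> GroupKey:
        return (self.cell_line, self.treated)


@dataclass
class StudyDesign:
    """Sample-to-group map plus phenotype roles.

    At least one treatment pair must carry role A; role-B pairs may number
    zero or more (with zero, the phenotype filter degenerates to an A-only
    consistency requirement).
    """

    groups: dict[GroupKey, list[str]]
    treatment_pairs: list[TreatmentPair]
    phenotype_roles: dict[str, str]
    min_replicates: int = 5

    def __post_init__(self) -> None:
        if self.min_replicates < 3:
            raise DesignError(
                "min_replicates must be >= 3; fewer replicates make every pair "
                "unclassifiable under the >=3-distinct-points rule"
            )
        seen: dict[str, GroupKey] = {}
        for key, members in self.groups.items():
            if len(members) < self.min_replicates:
                raise DesignError(
                    f"group {key} has {len(members)} samples, fewer than "
                    f"min_replicates={self.min_replicates}"
                )
            for s in members:
                if s in seen:
                    raise DesignError(f"sample {s!r} listed in both {seen[s]} and {key}")
                seen[s] = key
        for pair in self.treatment_pairs:
            for key in (pair.control_key, pair.treated_key):
                if key not in self.groups:
                    raise DesignError(f"treatment pair references unknown group {key}")
            if pair.cell_line not in self.phenotype_roles:
                raise DesignError(f"cell line {pair.cell_line!r} has no phenotype role")
        bad_roles = {
            cl: r for cl, r in self.phenotype_roles.items() if r not in (ROLE_A, ROLE_B)
        }
        if bad_roles:
            raise DesignError(f"phenotype roles must be 'A' or 'B', got {bad_roles}")
        if not self.a_pairs:
            raise DesignError("design must contain at least one Phenotype-A treatment pair")

    @property
    def a_pairs(self) -> list[TreatmentPair]:
        return sorted(
            (p for p in self.treatment_pairs if self.phenotype_roles[p.cell_line] == ROLE_A),
            key=lambda p: p.cell_line,
        )

    @property
    def b_pairs(self) -> list[TreatmentPair]:
        return sorted(
            (p for p in self.treatment_pairs if self.phenotype_roles[p.cell_line] == ROLE_B),
            key=lambda p: p.cell_line,
        )

    @property
    def sample_to_group(self) -> dict[str, GroupKey]:
        return {s: key for key, members in self.groups.items() for s in members}

    def to_dict(self) -> dict:
        return {
            "groups": [
                {"cell_line": cl, "treatment": trt, "samples": list(members)}
                for (cl, trt), members in self.groups.items()
            ],
            "treatment_pairs": [
                {"cell_line": p.cell_line, "control": p.control, "treated": p.treated}
                for p in self.treatment_pairs
            ],
            "phenotype_roles": dict(self.phenotype_roles),
            "min_replicates": self.min_replicates,
        }

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def design_from_dict(cfg: Mapping) -> StudyDesign:
    groups = {
        (str(g["cell_line"]), str(g["treatment"])): [str(s) for s in g["samples"]]
        for g in cfg["groups"]
    }
    pairs = [
        TreatmentPair(str(p["cell_line"]), str(p["control"]), str(p["treated"]))
        for p in cfg["treatment_pairs"]
    ]
    roles = {str(k): str(v) for k, v in cfg["phenotype_roles"].items()}
    return StudyDesign(
        groups=groups,
        treatment_pairs=pairs,
        phenotype_roles=roles,
        min_replicates=int(cfg.get("min_replicates", 5)),
    )


def read_design(path: str | Path) -> StudyDesign:
    """Read a YAML study-design config (groups / treatment_pairs / phenotype_roles)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise DesignError(f"design file {path} is not a mapping")
    return design_from_dict(cfg)


def template_design(
    a_lines: Sequence[str] = ("MDA-MB-231", "MDA-MB-157"),
    b_lines: Sequence[str] = ("Hs 578T",),
    control: str = "DMSO",
    treated: str = "GL24",
    n_replicates: int = 5,
) -> StudyDesign:
    """The documented default template: two effective lines, one non-effective
    line, a solvent control and one treatment, five replicates per group."""
    groups: dict[GroupKey, list[str]] = {}
    pairs: list[TreatmentPair] = []
    roles: dict[str, str] = {}
    for line, role in [(l, ROLE_A) for l in a_lines] + [(l, ROLE_B) for l in b_lines]:
        roles[line] = role
        for trt in (control, treated):
            groups[(line, trt)] = [f"{line}_{trt}_{i + 1}" for i in range(n_replicates)]
        pairs.append(TreatmentPair(line, control, treated))
    return StudyDesign(groups, pairs, roles, min_replicates=min(5, n_replicates))


@dataclass
class GroupMatrix:
    """Gene x replicate submatrix for one (cell line, treatment) group."""

    cell_line: str
    treatment: str
    values: pd.DataFrame

    @property
    def key(self) -> GroupKey:
        return (self.cell_line, self.treatment)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


def subset_group(
    matrix: ExpressionMatrix, design: StudyDesign, group: GroupKey
) -> GroupMatrix:
    """Column-slice the expression matrix down to one group; gene order is kept."""
    if group not in design.groups:
        raise DesignError(f"unknown group {group}")
    members = design.groups[group]
    missing = [s for s in members if s not in matrix.values.columns]
    if missing:
        raise DesignError(f"group {group} references samples absent from matrix: {missing}")
    return GroupMatrix(group[0], group[1], matrix.values.loc[:, members])
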