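"""Digital count matrices (targets x lanes) and the RCC interchange format.

The nCounter platform delivers one Reporter Code Count (RCC) file per lane: a
sectioned text file whose ``Code_Summary`` section is a CSV of
``CodeClass,Name,Accession,Count``. A :class:`CountMatrix` collects lanes
into a targets-by-samples table annotated with each target's code class and
a normalization stage tag; normalization stages must be applied in the fixed
order raw -> background_subtracted -> positive_normalized ->
reference_normalized.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

CODE_CLASSES = ("Endogenous", "Positive", "Negative", "Housekeeping")
STAGES = (
    "raw",
    "background_subtracted",
    "positive_normalized",
    "reference_normalized",
)


class CountMatrix:
    """Targets x samples digital counts with per-target code class.

    Parameters
    ----------
    counts
        DataFrame indexed by target name, one column per lane; nonnegative.
        Raw-stage counts are integers.
    code_class
        Series mapping target name -> code class (one of
        Endogenous/Positive/Negative/Housekeeping).
    stage
        Normalization stage tag.
    """

    def __init__(self, counts: pd.DataFrame, code_class: pd.Series, stage: str = "raw"):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        counts = counts.astype(float)
        code_class = code_class.reindex(counts.index)
        if code_class.isna().any():
            missing = list(code_class.index[code_class.isna()])
            raise ValueError(f"targets lack code class annotations: {missing}")
        unknown = set(code_class) - set(CODE_CLASSES)
        if unknown:
            raise ValueError(f"unknown code classes: {sorted(unknown)}")
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = counts
        self.code_class = code_class.astype(str)
        self.stage = stage
        # lane scale factors recorded by normalization steps, keyed by step name
        self.norm_factors: dict[str, pd.Series] = {}

    # ---- basic accessors ---------------------------------------------------

    @property
    def targets(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def class_targets(self, code_class: str) -> list[str]:
        return list(self.code_class.index[self.code_class == code_class])

    def class_counts(self, code_class: str) -> pd.DataFrame:
        return self.counts.loc[self.class_targets(code_class)]

    def copy_with(self, counts: pd.DataFrame, stage: str) -> "CountMatrix":
        out = CountMatrix(counts, self.code_class.copy(), stage)
        out.norm_factors = dict(self.norm_factors)
        return out

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(
                f"operation requires stage {stage!r}, matrix is at {self.stage!r}"
            )

    # ---- TSV ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "CodeClass", self.code_class)
        df.index.name = "Name"
        with open(path, "w") as fh:
            fh.write(f"# stage={self.stage}\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        stage = "raw"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# stage="):
                stage = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        code_class = df.pop("CodeClass")
        return cls(df, code_class, stage)


# ---- RCC -------------------------------------------------------------------


def write_rcc(
    matrix: CountMatrix,
    directory: str | Path,
    *,
    accession: str = "synthetic",
    sample_attrs: dict[str, str] | None = None,
) -> list[Path]:
    """Write one RCC file per lane; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, lane in enumerate(matrix.samples, start=1):
        path = directory / f"{lane}.rcc"
        with open(path, "w") as fh:
            fh.write("<Header>\nFileVersion,1.7\nSoftwareVersion,circdigit\n</Header>\n")
            fh.write("<Sample_Attributes>\n")
            fh.write(f"ID,{lane}\n")
            for key, val in (sample_attrs or {}).items():
                fh.write(f"{key},{val}\n")
            fh.write("</Sample_Attributes>\n")
            fh.write(f"<Lane_Attributes>\nID,{i}\n</Lane_Attributes>\n")
            fh.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
            for name in matrix.targets:
                cc = matrix.code_class[name]
                count = matrix.counts.at[name, lane]
                count_str = str(int(round(count))) if matrix.stage == "raw" else repr(count)
                fh.write(f"{cc},{name},{accession},{count_str}\n")
            fh.write("</Code_Summary>\n")
        paths.append(path)
    return paths


def parse_rcc(path: str | Path) -> tuple[dict[tuple[str, str, str], float], dict[str, dict[str, str]]]:
    """Parse one RCC file.

    Returns ``(counts, attributes)`` where counts is keyed by
    ``(CodeClass, Name, Accession)`` and attributes maps section name ->
    key/value dict. Malformed Code_Summary lines raise with their line number.
    """
    counts: dict[tuple[str, str, str], float] = {}
    attributes: dict[str, dict[str, str]] = {}
    section = None
    saw_code_summary = False
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("</") and line.endswith(">"):
                section = None
                continue
            if line.startswith("<") and line.endswith(">"):
                section = line[1:-1]
                if section == "Code_Summary":
                    saw_code_summary = True
                    header_seen = False
                else:
                    attributes.setdefault(section, {})
                continue
            if section is None:
                continue
            if section == "Code_Summary":
                fields = line.split(",")
                if not header_seen:
                    header_seen = True
                    if fields[:4] != ["CodeClass", "Name", "Accession", "Count"]:
                        raise ValueError(
                            f"{path}:{lineno}: unexpected Code_Summary header {line!r}"
                        )
                    continue
                if len(fields) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: malformed Code_Summary line {line!r}"
                    )
                cc, name, acc, count_str = fields
                try:
                    count = float(count_str)
                except ValueError as err:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric count {count_str!r}"
                    ) from err
                if count < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative count {count_str!r} for {name}"
                    )
                if cc not in CODE_CLASSES:
                    warnings.warn(f"{path}:{lineno}: unknown CodeClass {cc!r}")
                counts[(cc, name, acc)] = count
            else:
                key, _, val = line.partition(",")
                attributes.setdefault(section, {})[key] = val
    if not saw_code_summary:
        raise ValueError(f"{path}: missing Code_Summary section")
    return counts, attributes


def load_rcc_dir(directory: str | Path, pattern: str = "*.rcc") -> CountMatrix:
    """Load all RCC files in a directory into one raw CountMatrix.

    Lane ids come from each file's Sample_Attributes ID (falling back to the
    file stem); all lanes must share an identical target set.
    """
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no RCC files matching {pattern} in {directory}")
    return merge_rcc(paths)


def merge_rcc(paths: list[str | Path]) -> CountMatrix:
    lanes: dict[str, dict[tuple[str, str, str], float]] = {}
    for path in paths:
        counts, attrs = parse_rcc(path)
        lane_id = attrs.get("Sample_Attributes", {}).get("ID") or Path(path).stem
        lanes[lane_id] = counts
    keysets = [tuple(sorted(c.keys())) for c in lanes.values()]
    if len(set(keysets)) != 1:
        raise ValueError("RCC lanes do not share an identical target set")
    # preserve target order from the first file
    first = next(iter(lanes.values()))
    names = [name for (_, name, _) in first]
    code_class = pd.Series({name: cc for (cc, name, _) in first})
    df = pd.DataFrame(
        {lane: [c[key] for key in first] for lane, c in lanes.items()},
        index=names,
    )
    return CountMatrix(df, code_class, "raw")
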