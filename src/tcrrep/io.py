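"""File formats and the end-to-end pipeline runner.

Clonotype tables are tab-separated UTF-8 with AIRR-style column names
(repertoire_id, v_call, j_call, junction, junction_aa, productive,
duplicate_count, frequency), frequencies printed with 9 decimal places.
Every output file opens with a ``# key=value`` provenance comment block
(package version, seed, config echo) that TSV parsers configured to skip
``#`` lines pass over.  Outputs are pure functions of (inputs, config,
seed): repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

from .calling import Clonotype, ClonotypeTable, build_clonotype_table
from .compare import PairedComparison, compare_repertoires
from .germline import SegmentSet, load_segments, toy_reference
from .metrics import RepertoireSummary, spectratype, summarize, usage_matrix
from .simulate import SimulationConfig, emit_reads, preset_config, simulate_repertoire

logger = logging.getLogger(__name__)

try:
    __version__ = _pkg_version("tcrrep")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    __version__ = "unknown"

CLONOTYPE_COLUMNS = (
    "repertoire_id",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
    "frequency",
)
FREQUENCY_DECIMALS = 9
FREQUENCY_TOLERANCE = 5e-10


class ParseError(ValueError):
    """A pipeline file failed validation; message carries the line number."""


# ---------------------------------------------------------------------------
# Provenance headers
# ---------------------------------------------------------------------------

def _provenance_lines(provenance: dict | None) -> str:
    items = {"tcrrep_version": __version__}
    if provenance:
        items.update(provenance)
    return "".join(f"# {k}={v}\n" for k, v in items.items())


def read_provenance(path: str | Path) -> dict[str, str]:
    """Parse the leading ``# key=value`` comment block of a pipeline file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# Clonotype table TSV
# ---------------------------------------------------------------------------

def write_clonotype_table(
    table: ClonotypeTable, path: str | Path, provenance: dict | None = None
) -> None:
    """Write an AIRR-style clonotype TSV with a provenance header."""
    prov = {
        "sample_id": table.sample_id,
        "total_reads": table.total_reads,
        "assigned_reads": table.assigned_reads,
        "unassigned_reads": table.unassigned_reads,
    }
    if provenance:
        prov.update(provenance)
    total = table.assigned_reads
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(prov))
        fh.write("\t".join(CLONOTYPE_COLUMNS) + "\n")
        for c in table.clonotypes:
            freq = c.read_count / total
            fh.write(
                "\t".join(
                    (
                        table.sample_id,
                        c.v_call,
                        c.j_call,
                        c.junction_nt,
                        c.junction_aa if c.junction_aa is not None else "",
                        "T" if c.productive else "F",
                        str(c.read_count),
                        f"{freq:.{FREQUENCY_DECIMALS}f}",
                    )
                )
                + "\n"
            )


def read_clonotype_table(path: str | Path) -> ClonotypeTable:
    """Read and validate an AIRR-style clonotype TSV.

    Duplicate (v_call, j_call, junction) rows are merged with summed counts
    and a warning; a frequency column inconsistent with the counts beyond
    5e-10, missing columns, or non-numeric counts raise :class:`ParseError`
    with the offending line number.
    """
    path = Path(path)
    header_line = 0
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    columns: list[str] | None = None
    for lineno, line in enumerate(lines, 1):
        if line.startswith("#"):
            continue
        stripped = line.rstrip("\n")
        if columns is None:
            columns = stripped.split("\t")
            header_line = lineno
            continue
        if stripped:
            rows.append((lineno, stripped.split("\t")))
    if columns is None:
        raise ParseError(f"{path}: no header row found")
    missing = [c for c in CLONOTYPE_COLUMNS if c not in columns]
    if missing:
        raise ParseError(f"{path}:{header_line}: missing columns {', '.join(missing)}")
    if not rows:
        raise ParseError(f"{path}: no clonotype rows")
    col_idx = {c: columns.index(c) for c in CLONOTYPE_COLUMNS}

    parsed = []
    for lineno, fields in rows:
        if len(fields) < len(columns):
            raise ParseError(f"{path}:{lineno}: expected {len(columns)} columns, got {len(fields)}")
        try:
            count = int(fields[col_idx["duplicate_count"]])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric duplicate_count "
                f"{fields[col_idx['duplicate_count']]!r}"
            ) from None
        if count < 1:
            raise ParseError(f"{path}:{lineno}: duplicate_count must be a positive integer")
        try:
            freq = float(fields[col_idx["frequency"]])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric frequency {fields[col_idx['frequency']]!r}"
            ) from None
        prod_str = fields[col_idx["productive"]]
        if prod_str not in ("T", "F"):
            raise ParseError(f"{path}:{lineno}: productive must be 'T' or 'F', got {prod_str!r}")
        parsed.append(
            {
                "lineno": lineno,
                "repertoire_id": fields[col_idx["repertoire_id"]],
                "v_call": fields[col_idx["v_call"]],
                "j_call": fields[col_idx["j_call"]],
                "junction": fields[col_idx["junction"]],
                "junction_aa": fields[col_idx["junction_aa"]],
                "productive": prod_str == "T",
                "count": count,
                "frequency": freq,
            }
        )

    total = sum(r["count"] for r in parsed)
    for r in parsed:
        if abs(r["frequency"] - r["count"] / total) > FREQUENCY_TOLERANCE:
            raise ParseError(
                f"{path}:{r['lineno']}: frequency {r['frequency']} inconsistent with "
                f"duplicate_count/total = {r['count'] / total:.12f}"
            )

    merged: dict[tuple[str, str, str], dict] = {}
    for r in parsed:
        key = (r["v_call"], r["j_call"], r["junction"])
        if key in merged:
            merged[key]["count"] += r["count"]
            warnings.warn(
                f"{path}:{r['lineno']}: duplicate clonotype row {key} merged", stacklevel=2
            )
        else:
            merged[key] = r

    prov = read_provenance(path)
    sample_id = prov.get("sample_id", parsed[0]["repertoire_id"])
    total_reads = int(prov.get("total_reads", total))
    unassigned = int(prov.get("unassigned_reads", total_reads - total))

    clonotypes = [
        Clonotype(
            v_call=key[0],
            j_call=key[1],
            junction_nt=key[2],
            junction_aa=r["junction_aa"] or None,
            productive=r["productive"],
            read_count=r["count"],
        )
        for key, r in merged.items()
    ]
    clonotypes.sort(key=lambda c: (-c.read_count, c.key))
    return ClonotypeTable(
        sample_id=sample_id,
        clonotypes=clonotypes,
        total_reads=total_reads,
        assigned_reads=total,
        unassigned_reads=unassigned,
    )


# ---------------------------------------------------------------------------
# Derived-output writers
# ---------------------------------------------------------------------------

def write_summary(summary: RepertoireSummary, path: str | Path, provenance: dict | None = None) -> None:
    prov = {"sample_id": summary.sample_id, "productive_only": summary.productive_only}
    if provenance:
        prov.update(provenance)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(prov))
        fh.write("metric\tvalue\n")
        for name, value in summary.to_records():
            fh.write(f"{name}\t{value:.9g}\n")


def write_spectratype(profile, path: str | Path, provenance: dict | None = None) -> None:
    prov = {
        "sample_id": profile.sample_id,
        "productive_only": profile.productive_only,
        "weight": profile.weight,
        "modal_length": profile.modal_length,
    }
    if provenance:
        prov.update(provenance)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(prov))
        fh.write("length\tfraction\n")
        for length in sorted(profile.fractions):
            fh.write(f"{length}\t{profile.fractions[length]:.9f}\n")


def write_usage_matrix(usage, path: str | Path, provenance: dict | None = None) -> None:
    prov = {"sample_id": usage.sample_id}
    if provenance:
        prov.update(provenance)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(prov))
        fh.write("v_call\t" + "\t".join(usage.matrix.columns) + "\n")
        for v_gene, row in usage.matrix.iterrows():
            fh.write(v_gene + "\t" + "\t".join(f"{x:.9f}" for x in row.values) + "\n")


def write_comparison(comparison: PairedComparison, out_dir: str | Path, provenance: dict | None = None) -> None:
    """Write fold-change and delta-summary TSVs for one paired comparison."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = {"subject_id": comparison.subject_id}
    if provenance:
        prov.update(provenance)

    fold_path = out_dir / "fold_changes.tsv"
    with open(fold_path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(prov))
        fh.write("v_call\tj_call\tjunction\tpre_freq\tpost_freq\tfold\tstatus\tcensored\n")
        for _, row in comparison.fold_table.iterrows():
            fh.write(
                f"{row.v_call}\t{row.j_call}\t{row.junction}\t"
                f"{row.pre_freq:.9f}\t{row.post_freq:.9f}\t{row.fold:.6g}\t"
                f"{row.status}\t{'T' if row.censored else 'F'}\n"
            )

    delta_path = out_dir / "deltas.tsv"
    d = comparison.diversity
    records = [
        ("n_shared", len(comparison.shared)),
        ("n_gained", len(comparison.gained)),
        ("n_lost", len(comparison.lost)),
        ("pre_inverse_simpson", comparison.pre_summary.inverse_simpson),
        ("post_inverse_simpson", comparison.post_summary.inverse_simpson),
        ("d_inverse_simpson", d.d_inverse_simpson),
        ("pre_shannon", comparison.pre_summary.shannon),
        ("post_shannon", comparison.post_summary.shannon),
        ("d_shannon", d.d_shannon),
        ("inverse_simpson_ratio", d.inverse_simpson_ratio),
        ("shannon_ratio", d.shannon_ratio),
        ("pre_max_clone_freq", comparison.pre_summary.max_clone_freq),
        ("post_max_clone_freq", comparison.post_summary.max_clone_freq),
    ]
    if comparison.marker_bias_delta is not None:
        records.append(("marker_bias_delta", comparison.marker_bias_delta))
    with open(delta_path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(prov))
        fh.write("metric\tvalue\n")
        for name, value in records:
            fh.write(f"{name}\t{value:.9g}\n")

    shift_path = out_dir / "usage_shift.tsv"
    with open(shift_path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(prov))
        fh.write("gene\tkind\tusage_delta\n")
        for gene, delta in comparison.v_usage_shift.items():
            fh.write(f"{gene}\tV\t{delta:.9f}\n")
        for gene, delta in comparison.j_usage_shift.items():
            fh.write(f"{gene}\tJ\t{delta:.9f}\n")


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of one pipeline invocation."""

    command: str  # "simulate" | "call" | "metrics" | "compare"
    out_dir: Path
    seed: int = 0
    preset: str | None = None
    sim_config: SimulationConfig | None = None
    reads_path: Path | None = None
    reference_path: Path | None = None
    anchors_path: Path | None = None
    table_path: Path | None = None
    pre_path: Path | None = None
    post_path: Path | None = None
    sample_id: str = "sample"
    threshold: float = 0.01
    top_n: int = 10
    productive_only: bool = True
    n_clonotypes: int | None = None  # preset overrides for the simulate command
    read_depth: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def _load_reference(config: RunConfig) -> SegmentSet:
    if config.reference_path is None:
        return toy_reference()
    return load_segments(config.reference_path, config.anchors_path)


def run_pipeline(config: RunConfig) -> Path:
    """Execute one pipeline stage composition; returns the output directory.

    ``simulate``: simulate -> emit reads -> call -> metrics (single sample).
    ``call``: reads -> clonotype table.  ``metrics``: table -> summary,
    spectratype, usage matrix.  ``compare``: two tables -> paired comparison.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "command": config.command}

    if config.command == "simulate":
        sim_cfg = config.sim_config
        if sim_cfg is None:
            if config.preset is None:
                raise ValueError("simulate requires a preset or an explicit SimulationConfig")
            overrides = {}
            if config.n_clonotypes is not None:
                overrides["n_clonotypes"] = config.n_clonotypes
            if config.read_depth is not None:
                overrides["read_depth"] = config.read_depth
            sim_cfg = preset_config(config.preset, seed=config.seed, **overrides)
        prov.update(
            {
                "preset": config.preset or "custom",
                "n_clonotypes": sim_cfg.n_clonotypes,
                "read_depth": sim_cfg.read_depth,
                "error_rate": sim_cfg.error_rate,
                "trim_mean": sim_cfg.trim_mean,
                "insert_mean": sim_cfg.insert_mean,
            }
        )
        truth = simulate_repertoire(sim_cfg)
        fastq = out / "reads.fastq"
        labels = out / "labels.tsv"
        counts = emit_reads(truth, sim_cfg, fastq, labels)
        truth_table = truth.to_clonotype_table(config.sample_id + "_truth", counts)
        write_clonotype_table(truth_table, out / "truth_clonotypes.tsv", prov)
        table = build_clonotype_table(fastq, sim_cfg.segment_set, config.sample_id)
        write_clonotype_table(table, out / "clonotypes.tsv", prov)
        _write_metrics_outputs(table, out, config, prov)
    elif config.command == "call":
        if config.reads_path is None:
            raise ValueError("call requires --reads")
        segments = _load_reference(config)
        table = build_clonotype_table(config.reads_path, segments, config.sample_id)
        write_clonotype_table(table, out / "clonotypes.tsv", prov)
    elif config.command == "metrics":
        if config.table_path is None:
            raise ValueError("metrics requires an input clonotype table")
        table = read_clonotype_table(config.table_path)
        _write_metrics_outputs(table, out, config, prov)
    elif config.command == "compare":
        if config.pre_path is None or config.post_path is None:
            raise ValueError("compare requires --pre and --post tables")
        pre = read_clonotype_table(config.pre_path)
        post = read_clonotype_table(config.post_path)
        comparison = compare_repertoires(
            pre,
            post,
            productive_only=config.productive_only,
            thresholds=(config.threshold,),
            top_ns=(config.top_n,),
        )
        write_comparison(comparison, out, prov)
    else:
        raise ValueError(f"unknown command {config.command!r}")
    logger.info("%s outputs written to %s", config.command, out)
    return out


def _write_metrics_outputs(table: ClonotypeTable, out: Path, config: RunConfig, prov: dict) -> None:
    summary = summarize(
        table,
        productive_only=config.productive_only,
        thresholds=(config.threshold,),
        top_ns=(config.top_n,),
    )
    write_summary(summary, out / "summary.tsv", prov)
    write_spectratype(
        spectratype(table, productive_only=config.productive_only),
        out / "spectratype.tsv",
        prov,
    )
    write_usage_matrix(usage_matrix(table, config.productive_only), out / "usage_matrix.tsv", prov)
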