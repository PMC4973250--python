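"""FASTA / Newick / TSV input-output.

Every text output starts with ``#`` header comments naming the producing
subcommand, a short config hash and the seed (Newick files use a bracketed
comment instead, which Newick parsers treat as whitespace), so any result
file can be traced back to the run that produced it.
"""

from __future__ import annotations

import io
import json
import hashlib
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .spectrum import AbundanceSpectrum, BinnedSpectrum

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_newick",
    "write_spectrum_tsv",
    "read_spectrum_tsv",
    "write_curve_tsv",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-FASTA file into (identifier, uppercased sequence) pairs."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        # fasta-pearson: standard records but tolerant of leading comment
        # lines (our own writers put provenance headers there)
        records = list(SeqIO.parse(str(path), "fasta-pearson"))
    except ValueError as exc:  # malformed record
        raise InputError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        # distinguish empty files from files with no '>' header at all
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip() and not line.startswith((">", "#", ";")):
                    raise InputError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
        raise InputError(f"no FASTA records in {path}")
    return [(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(records, path, meta: dict | None = None) -> None:
    """Write (identifier, sequence) pairs as FASTA (60-column wrap)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        seq_records = [
            SeqRecord(Seq(seq), id=str(name), description="") for name, seq in records
        ]
        SeqIO.write(seq_records, fh, "fasta")


def write_newick(tree, path, meta: dict | None = None) -> None:
    """Write a BranchingTree as Newick; run metadata goes into a leading
    bracket comment (legal Newick, ignored by parsers)."""
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            inner = " ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"[{inner}]\n")
        fh.write(tree.to_newick() + "\n")


def write_spectrum_tsv(spectrum, path, meta: dict | None = None) -> None:
    """Write a spectrum as TSV: k, s_or_bin_center, n, density.

    Works for both raw (:class:`AbundanceSpectrum`, unit-width rows) and
    log-binned (:class:`BinnedSpectrum`) spectra.  Fixed 6-decimal floats
    keep the files diffable.
    """
    buf = io.StringIO()
    buf.write(_header(meta))
    buf.write("k\ts_or_bin_center\tn\tdensity\n")
    if isinstance(spectrum, AbundanceSpectrum):
        for s in sorted(spectrum.entries):
            n = spectrum.entries[s]
            buf.write(f"{spectrum.k}\t{s:.6f}\t{n}\t{float(n):.6f}\n")
    elif isinstance(spectrum, BinnedSpectrum):
        for c, m, d in zip(spectrum.centers, spectrum.mass, spectrum.density):
            buf.write(f"{spectrum.k}\t{c:.6f}\t{int(m)}\t{d:.6f}\n")
    else:
        raise InputError(f"not a spectrum: {type(spectrum).__name__}")
    Path(path).write_text(buf.getvalue())


def read_spectrum_tsv(path) -> AbundanceSpectrum:
    """Read back an *unbinned* spectrum TSV written by write_spectrum_tsv."""
    entries: dict[int, int] = {}
    k = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("k\t") or not line.strip():
                continue
            k_str, s_str, n_str, _ = line.rstrip("\n").split("\t")
            k = int(k_str)
            s = float(s_str)
            if s != int(s):
                raise InputError(f"{path}: binned spectra cannot be read back exactly")
            entries[int(s)] = int(n_str)
    if k is None:
        raise InputError(f"{path}: no spectrum rows")
    return AbundanceSpectrum(k=k, entries=entries)


def write_curve_tsv(curve, path, meta: dict | None = None) -> None:
    """Write an ExponentCurve as TSV: k, alpha_hat, n_tail, stderr."""
    buf = io.StringIO()
    buf.write(_header(meta))
    buf.write("k\talpha_hat\tn_tail\tstderr\n")
    for k, a, n, se in zip(curve.k, curve.alpha, curve.n_tail, curve.stderr):
        buf.write(f"{k}\t{a:.6f}\t{n}\t{se:.6f}\n")
    Path(path).write_text(buf.getvalue())
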