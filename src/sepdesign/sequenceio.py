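"""Tiny FASTA helpers for CLI output (plain text, no dependencies)."""

from __future__ import annotations


def write_fasta_record(fh, header: str, seq: str, width: int = 70) -> None:
    fh.write(f">{header}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")
    if not seq:
        fh.write("\n")
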