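"""Bundled synthetic germline V/J mini-reference.

A small IMGT-flavoured reference (10 V and 6 J segments per receptor class)
generated from a fixed internal seed, so it is bit-identical everywhere and
needs no external downloads.  Random independent sequences are ~25% pairwise
identical, so the reference is well separated: nearest-germline assignment is
unambiguous at realistic substitution rates.
"""

from __future__ import annotations

from io import StringIO

from Bio import SeqIO

from ._util import derive_rng, random_nt

_REFERENCE_SEED = 20240611  # fixed; not a user-facing knob

V_LENGTH = 210
J_LENGTH = 48
N_V = 10
N_J = 6

LOCI = ("TRA", "TRB", "IGH", "IGK")


def _build() -> dict[str, dict[str, dict[str, str]]]:
    ref: dict[str, dict[str, dict[str, str]]] = {}
    for locus in LOCI:
        rng = derive_rng(_REFERENCE_SEED, "germline", locus)
        v = {f"{locus}V1-{i + 1}*01": random_nt(rng, V_LENGTH) for i in range(N_V)}
        j = {f"{locus}J{i + 1}*01": random_nt(rng, J_LENGTH) for i in range(N_J)}
        ref[locus] = {"V": v, "J": j}
    return ref


_REFERENCE = _build()


def reference_segments(locus: str, region: str) -> dict[str, str]:
    """Name -> sequence map for a locus ('TRA','TRB','IGH','IGK') and region ('V'/'J')."""
    return dict(_REFERENCE[locus][region])


def reference_fasta() -> str:
    """The whole mini-reference as FASTA text (names sorted within locus/region)."""
    out = []
    for locus in LOCI:
        for region in ("V", "J"):
            for name, seq in _REFERENCE[locus][region].items():
                out.append(f">{name}\n{seq}\n")
    return "".join(out)


def load_reference_fasta(path_or_text) -> dict[str, dict[str, str]]:
    """Parse a germline FASTA into {'V': {name: seq}, 'J': {name: seq}}.

    Segment class is read from the gene name (…V… vs …J… after the locus
    prefix), matching IMGT naming.
    """
    if hasattr(path_or_text, "read"):
        handle = path_or_text
    else:
        text = str(path_or_text)
        if text.lstrip().startswith(">"):
            handle = StringIO(text)
        else:
            handle = open(text)
    ref: dict[str, dict[str, str]] = {"V": {}, "J": {}}
    for rec in SeqIO.parse(handle, "fasta"):
        name = rec.id
        region = "V" if "V" in name[3:] or name[3] == "V" else "J"
        # gene symbol like IGHV1-1*01 / IGHJ4*01: 4th char is the region letter
        region = name[3] if len(name) > 3 and name[3] in "VJ" else region
        ref[region][name] = str(rec.seq).upper()
    if not ref["V"] or not ref["J"]:
        raise ValueError("germline reference must contain at least one V and one J segment")
    return ref
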