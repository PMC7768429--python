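"""Fetch a nucleotide sequence from the EMBL-EBI ENA browser API.

Used to compute descriptive statistics of a deposited genome accession
directly from the public archive; requires network access.
"""

from __future__ import annotations

import io
import urllib.request

from Bio import SeqIO

from .io_formats import SequenceRecord

ENA_FASTA_URL = "https://www.ebi.ac.uk/ena/browser/api/fasta/{accession}"


def fetch_sequence(accession: str, timeout: float = 60.0) -> SequenceRecord:
    """Download one accession as FASTA and return it as a SequenceRecord."""
    url = ENA_FASTA_URL.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records returned for {accession}")
    rec = records[0]
    return SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
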