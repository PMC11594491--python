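"""Packaged transcription of the published multi-method comparison table.

Eighteen rows — eight field-collected 1016G-candidate mosquitoes plus
additional field samples from three Osceola County (FL) collections, five
genotype-defined control strains/mixes and a nuclease-free-water blank —
each genotyped by melt-curve assay (MCA), 1016 allele-specific PCR, Sanger
sequencing and barcoded amplicon NGS, with COI species verification.  Cell
strings are kept character-for-character as printed, including ``no call``,
``not tested`` and weak-band annotations; an embedded checksum guards the
transcription against accidental edits.
"""

from __future__ import annotations

import hashlib
import io

from .records import SampleRecord, read_records_tsv

__all__ = ["TABLE1_TSV", "load_table1"]

TABLE1_TSV = """\
Sample\tMCA 1016/1534\tAS-PCR 1016\tSanger 1016\tNGS 989/1016/1534\tCOI Accession-%ID
Osceola 1\tIICC\tno call\tno call\tnot tested\tnot tested
Osceola 1\tGIFC\tno call\tno call\tno call\tMN299016.1-100%
Osceola 1\tGIFC\tweakV G\tGI\tSSGIFC\tMK300224.1-99.72%
Osceola 1\tGIFC\tweakG\tno call\tPPGICC\tMN299016.1-99.57%
Osceola 1\tVICC\tweakV\tno call\tno call\tMN299016.1-100%
Osceola 2\tGIFC\tweakV G\tGI\tSPGIFC\tMK300218.1-98.87%
Osceola 2\tGIFC\tG\tGI\tSSGIFC\tPP902511.1-99.57%
Osceola 2\tVICC\tV\tno call\tSSVICC\tMN299016.1-100%
Control-SSVVFF\tVVFF\tV\tVV\tSSVVFF\tMN299016.1-99.57%
Control-SSIICC\tIICC\tweakV\tII\tSSIICC\tMN299016.1-100%
Control-PPGGFF\tGGFF\tG\tGG\tPPGGFF\tMK300224.1-99.72%
Control-SSVIFC\tVIFC\tV\tVI\tSSVIFC\tMK300224.1-98.03%
Control-SSVIFC\tVIFC\tV\tVI\tnot tested\tnot tested
Control-SPGIFC\tIIFC\tno call\tII\tSSIICC\tMK300224.1-99.72%
Control-NFW\tno call\tno call\tno call\tno call\tno call
Osceola 3\tGIFC\tno call\tno call\tno call\tno call
Osceola 3\tGIFC\tno call\tno call\tSSGGFC\tPP902511.1-99.72%
Osceola 3\tVGFC\tV G\tG\tSPVGFC\tMN299016.1-100%
"""

#: sha256 of the transcription above; load_table1 refuses to run on a mismatch.
TABLE1_SHA256 = "b490173e2c53015f2897394a2fcef612d0febe4a02fed85e99e4c95eec4546a1"


def load_table1() -> list[SampleRecord]:
    """Load the packaged 18-row comparison table as sample records.

    Sample ids are formed as ``"<site> #<k>"`` since the printed table labels
    rows only by collection site.  Raises ``ValueError`` if the packaged text
    no longer matches its checksum.
    """
    digest = hashlib.sha256(TABLE1_TSV.encode()).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError("packaged comparison-table transcription failed its checksum")
    records = read_records_tsv(io.StringIO(TABLE1_TSV))
    if len(records) != 18:
        raise ValueError(f"expected 18 rows, parsed {len(records)}")
    return records
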