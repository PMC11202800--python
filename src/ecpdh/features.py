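"""Assembly of full feature tables from residue records."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datamodel import FeatureTable, ResidueRecord, assemble_features, records_to_table
from .emd import EMDConfig, extract_emd_block
from .schema import FeatureSchema, build_default_schema
from .wavelet import WaveletConfig, extract_wavelet_block


def build_feature_table(
    records: Sequence[ResidueRecord],
    schema: FeatureSchema | None = None,
    emd_config: EMDConfig | None = None,
    wavelet_config: WaveletConfig | None = None,
) -> FeatureTable:
    """Compute wavelet and EMD blocks per record and assemble the full
    feature matrix (218 columns under the default schema)."""
    schema = schema or build_default_schema()
    emd_config = emd_config or EMDConfig()
    wavelet_config = wavelet_config or WaveletConfig()
    rows = np.empty((len(records), len(schema)))
    for i, rec in enumerate(records):
        wav = extract_wavelet_block(rec, wavelet_config)
        emd = extract_emd_block(rec, emd_config)
        rows[i] = assemble_features(rec, wav, emd, schema)
    return records_to_table(records, schema, rows)
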