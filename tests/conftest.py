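import pytest

from ccfdna.panel import MarkerDefinition, MarkerPanel, default_panel


@pytest.fixture(scope="session")
def panel() -> MarkerPanel:
    return default_panel()


@pytest.fixture(scope="session")
def single_marker_panel(panel) -> MarkerPanel:
    """One-marker panel: cheap end-to-end runs where only fractions matter."""
    return MarkerPanel(markers=(panel.markers[0],), version="single")


@pytest.fixture
def toy_marker() -> MarkerDefinition:
    """Hand-built 60 bp marker with 3 CpGs and CH-rich primers.

    Layout: 15 bp forward primer, interior with CpGs at 20, 30, 40,
    15 bp reverse primer.
    """
    primer_f = "ACTACTCATCATCTA"  # 4 CH cytosines, no CG
    primer_r = "TCATCATCTATAACT"  # 4 CH cytosines, no CG
    interior = "ATTAACGATTATTTTACGATTATTTTCGAA"
    seq = primer_f + interior + primer_r
    cpgs = tuple(i for i in range(len(seq)) if seq[i : i + 2] == "CG")
    marker = MarkerDefinition(
        name="toy",
        reference_seq=seq,
        cpg_positions=cpgs,
        primer_fwd_span=(0, len(primer_f)),
        primer_rev_span=(len(seq) - len(primer_r), len(seq)),
        barcode="AGTAGTAA",
    )
    marker.validate()
    return marker
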