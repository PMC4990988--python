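import gemmi
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


@pytest.fixture
def make_synthetic_pdb(tmp_path):
    """Write a minimal synthetic poly-ALA PDB (one CA atom per residue) and
    return its path. Purely a structural scaffold for annotation tests."""

    def _make(residue_ids, name="synthetic_scaffold.pdb"):
        st = gemmi.Structure()
        st.name = "synthetic"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        for i, rid in enumerate(residue_ids):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(rid, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(float(i), 0.0, 0.0)
            atom.occ = 1.0
            atom.b_iso = 50.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        path = tmp_path / name
        st.write_pdb(str(path))
        return path

    return _make
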