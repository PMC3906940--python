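import pytest

import salmodiv as sd

# Dated salmonid-like species tree: three subfamilies with two species each
# (crown 52 Ma), plus two successive outgroups diverging before the WGD.
SPECIES_NEWICK = (
    "((((Salmo:20,Oncorhynchus:20):32,"
    "((Thymallus:25,Thymallus_arcticus:25):15,"
    "(Coregonus:30,Coregonus_albula:30):10):12):58,Esox:110):15,Osmerus:125);"
)

SUBFAMILY_OF = {
    "Salmo": "Salmoninae",
    "Oncorhynchus": "Salmoninae",
    "Thymallus": "Thymallinae",
    "Thymallus_arcticus": "Thymallinae",
    "Coregonus": "Coregoninae",
    "Coregonus_albula": "Coregoninae",
}

OUTGROUPS = ("Esox", "Osmerus")

# crown children of the ingroup, keyed by their alphabetically-first tip
LINEAGE_SALMONINAE = "Oncorhynchus"
LINEAGE_THY_COR = "Coregonus"


@pytest.fixture
def species_tree():
    return sd.read_newick(SPECIES_NEWICK)


@pytest.fixture
def subfamily_of():
    return dict(SUBFAMILY_OF)


def make_scenario_spec(scenario, **kwargs):
    defaults = dict(wgd_depth=95.0, outgroups=OUTGROUPS)
    if scenario == "b_ancestral_DR":
        defaults["dr_depths"] = 90.0
    elif scenario == "c_lineage_specific_DR":
        defaults["dr_depths"] = {LINEAGE_SALMONINAE: 45.0, LINEAGE_THY_COR: 48.0}
    elif scenario == "d_unresolved_tetrasomic":
        defaults["dr_depths"] = {LINEAGE_SALMONINAE: None, LINEAGE_THY_COR: 48.0}
        defaults["conversion_strength"] = 1.0
    defaults.update(kwargs)
    return sd.WgdScenarioSpec(scenario=scenario, **defaults)


def gene_tree_taxon_map(gene_tree):
    tips = [leaf.taxon.label for leaf in gene_tree.leaf_node_iter()]
    return sd.TaxonMap.from_subfamilies(tips, SUBFAMILY_OF, outgroups=OUTGROUPS)
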