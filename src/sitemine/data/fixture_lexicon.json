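{
  "comment": "Synthetic miniature synset forest for offline semantic-similarity scoring. Hand-built: four hypernym trees (contact phenomena, chemical processes, substances, attributes), one gloss and one corpus count per synset. Glosses of contact/site synsets deliberately share the stock phrase 'where two molecules come into physical contact' so that gloss-overlap (Lesk) scores separate them from the other trees.",
  "synsets": [
    {"id": "phenomenon", "words": ["phenomenon"], "hypernym": null, "count": 20,
     "gloss": "something that can be observed to happen between bodies"},
    {"id": "interaction", "words": ["interaction", "interplay"], "hypernym": "phenomenon", "count": 10,
     "gloss": "a mutual action where two molecules come into physical contact"},
    {"id": "contact", "words": ["contact", "touch"], "hypernym": "interaction", "count": 10,
     "gloss": "the state where two molecules come into physical contact across their surfaces"},
    {"id": "binding", "words": ["binding", "association", "attachment"], "hypernym": "interaction", "count": 10,
     "gloss": "the specific joining where two molecules come into physical contact and one attaches to the other"},
    {"id": "docking", "words": ["docking"], "hypernym": "binding", "count": 10,
     "gloss": "the fitting where two molecules come into physical contact in a predicted orientation"},
    {"id": "recognition", "words": ["recognition"], "hypernym": "interaction", "count": 10,
     "gloss": "the selective identification by which two molecules come into physical contact"},
    {"id": "place", "words": ["place", "location"], "hypernym": "phenomenon", "count": 10,
     "gloss": "a point or extent in space that can be occupied"},
    {"id": "site", "words": ["site", "spot"], "hypernym": "place", "count": 10,
     "gloss": "a region on a protein where two molecules come into physical contact"},
    {"id": "binding_site", "words": ["interface"], "hypernym": "site", "count": 10,
     "gloss": "the region on a protein surface where two molecules come into physical contact during binding"},
    {"id": "pocket", "words": ["pocket", "groove", "cavity", "cleft"], "hypernym": "site", "count": 10,
     "gloss": "a recessed region where two molecules come into physical contact and one is held"},
    {"id": "region", "words": ["region", "area"], "hypernym": "place", "count": 10,
     "gloss": "an extent of space on or within something"},
    {"id": "surface", "words": ["surface"], "hypernym": "region", "count": 10,
     "gloss": "the outer boundary region of an object where two molecules come into physical contact"},

    {"id": "process", "words": ["process"], "hypernym": null, "count": 20,
     "gloss": "a sustained change unfolding through time"},
    {"id": "modification", "words": ["modification"], "hypernym": "process", "count": 10,
     "gloss": "a chemical change in which a group is added to a molecule"},
    {"id": "phosphorylation", "words": ["phosphorylation"], "hypernym": "modification", "count": 10,
     "gloss": "the addition of a phosphate group to a molecule"},
    {"id": "glycosylation", "words": ["glycosylation"], "hypernym": "modification", "count": 10,
     "gloss": "the addition of a sugar group to a molecule"},
    {"id": "ubiquitination", "words": ["ubiquitination", "sumoylation"], "hypernym": "modification", "count": 10,
     "gloss": "the addition of a small protein tag to a molecule"},
    {"id": "dissociation", "words": ["dissociation"], "hypernym": "process", "count": 10,
     "gloss": "the separation of a bound assembly into its parts"},
    {"id": "mutation", "words": ["mutation"], "hypernym": "process", "count": 10,
     "gloss": "a permanent change in the sequence of a gene or a protein"},
    {"id": "folding", "words": ["folding"], "hypernym": "process", "count": 10,
     "gloss": "the change by which a chain acquires its native shape"},

    {"id": "matter", "words": ["matter", "substance"], "hypernym": null, "count": 20,
     "gloss": "that which occupies space and has mass"},
    {"id": "molecule", "words": ["molecule"], "hypernym": "matter", "count": 10,
     "gloss": "the smallest unit of a compound made of bonded atoms"},
    {"id": "protein", "words": ["protein"], "hypernym": "molecule", "count": 10,
     "gloss": "a chain of amino acids folded into a working shape"},
    {"id": "enzyme", "words": ["enzyme"], "hypernym": "protein", "count": 10,
     "gloss": "a protein that speeds a chemical reaction"},
    {"id": "receptor", "words": ["receptor"], "hypernym": "protein", "count": 10,
     "gloss": "a protein that receives and transmits a signal"},
    {"id": "antibody", "words": ["antibody"], "hypernym": "protein", "count": 10,
     "gloss": "a protein of the immune system that marks foreign material"},
    {"id": "ligand", "words": ["ligand"], "hypernym": "molecule", "count": 10,
     "gloss": "a molecule that is held by a larger partner"},
    {"id": "nucleotide", "words": ["nucleotide"], "hypernym": "molecule", "count": 10,
     "gloss": "a building block of nucleic acids"},
    {"id": "water", "words": ["water", "solvent"], "hypernym": "molecule", "count": 10,
     "gloss": "the liquid medium surrounding dissolved material"},
    {"id": "residue", "words": ["residue"], "hypernym": "molecule", "count": 10,
     "gloss": "an amino acid unit within a protein chain"},
    {"id": "atom", "words": ["atom"], "hypernym": "matter", "count": 10,
     "gloss": "the smallest unit of an element"},

    {"id": "attribute", "words": ["attribute", "property"], "hypernym": null, "count": 20,
     "gloss": "a quality belonging to a thing"},
    {"id": "affinity", "words": ["affinity"], "hypernym": "attribute", "count": 10,
     "gloss": "the strength with which partners hold together"},
    {"id": "stability", "words": ["stability"], "hypernym": "attribute", "count": 10,
     "gloss": "the resistance of a folded chain to unfolding"},
    {"id": "energy", "words": ["energy"], "hypernym": "attribute", "count": 10,
     "gloss": "the capacity to do work"},
    {"id": "shape", "words": ["shape", "conformation"], "hypernym": "attribute", "count": 10,
     "gloss": "the spatial arrangement of a body"},
    {"id": "hydrophobicity", "words": ["hydrophobicity"], "hypernym": "attribute", "count": 10,
     "gloss": "the tendency of a group to avoid the liquid medium"}
  ]
}
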