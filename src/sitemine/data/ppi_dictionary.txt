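# Binding-site keyword dictionary (lemmas / stem words).
# [positive] = relevant to the protein-protein binding site (PPI+ive)
# [negative] = indicates interaction context only, not the binding site (PPI-ive)
[positive]
bind
interfac
complex
hydrophob
recept
ligand
contact
recog
dock
groove
pocket
pouch
interact
crystal
latch
catal
[negative]
deamidation
IgM
IgG
dissociat
antibo
alloster
phosphory
nucleotide
polar
dCTP
dATP
dTTP
dUTP
dGTP
IgG1
IgG2
IgG3
IgG4
Fc
ubiquitin
neddylat
sumoyla
glycosylation
lipidation
carbonylation
nitrosylation
epitope
paratope
purine
pyrimidine
isomeriz
non-conserved
fucosylated
nonfucosylated
sialylation
galactosylation
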