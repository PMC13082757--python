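alias,species
human,human
humans,human
homo sapiens,human
man,human
patient,human
patients,human
mouse,mouse
mice,mouse
mus musculus,mouse
rat,rat
rats,rat
rattus norvegicus,rat
rabbit,rabbit
rabbits,rabbit
oryctolagus cuniculus,rabbit
dog,dog
dogs,dog
beagle,dog
beagle dog,dog
canine,dog
canis familiaris,dog
monkey,monkey
monkeys,monkey
cynomolgus monkey,monkey
cynomolgus,monkey
rhesus monkey,monkey
rhesus,monkey
macaque,monkey
non-human primate,monkey
nhp,monkey
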