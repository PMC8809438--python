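# Geographical-origin category -> supergroup map for clade tables.
# Editable: any category used in a clade table must appear here (or be the
# literal "Unknown").  Categories reflect published phylogeographic source
# areas for Northern-Hemisphere mountain floras.
Eastern Asia: Laurasian
Tethyan: Laurasian
North America: Laurasian
Southwest Asia: Laurasian
Central Asia: Laurasian
Eurasia: Laurasian
Southwest China: Laurasian
Northwest China: Laurasian
Qinghai-Tibet plateau: Laurasian
Eastern Asia or Western North America: Laurasian
Central Asia or the Qinghai-Tibet plateau: Laurasian
Northern Hemisphere unknown: Laurasian
Africa: Gondwanan
Southern Hemisphere unknown: Gondwanan
Unknown: Unknown
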