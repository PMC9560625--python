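group_name	member_taxon
Bos/Bison	Bos primigenius
Bos/Bison	Bison priscus
Cervidae	Cervus elaphus
Cervidae	Capreolus capreolus
Caprinae/Cervidae	Caprinae
Caprinae/Cervidae	Cervidae
Bovidae/Caprinae	Bos/Bison
Bovidae/Caprinae	Caprinae
Bovidae/Caprinae/Cervidae	Bos/Bison
Bovidae/Caprinae/Cervidae	Caprinae
Bovidae/Caprinae/Cervidae	Cervidae
Ursus sp./Lynx lynx	Ursus sp.
Ursus sp./Lynx lynx	Lynx lynx
Carnivora	Canis lupus
Carnivora	Vulpes vulpes
Carnivora	Ursus sp.
Carnivora	Lynx lynx
Carnivora	Felis silvestris
Carnivora/Sus scrofa/Lepus sp.	Carnivora
Carnivora/Sus scrofa/Lepus sp.	Sus scrofa
Carnivora/Sus scrofa/Lepus sp.	Lepus sp.
Ungulata	Equus ferus
Ungulata	Sus scrofa
Ungulata	Bos/Bison
Ungulata	Caprinae/Cervidae
Mammalia	Ungulata
Mammalia	Carnivora
Mammalia	Lepus sp.
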