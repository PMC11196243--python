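species,genus,family,native,zones
Achyrachaena mollis,Achyrachaena,Asteraceae,Yes,U;E
Alopecurus pratensis,Alopecurus,Poaceae,No,U
Amsinckia menziesii,Amsinckia,Boraginaceae,Yes,U
Avena fatua,Avena,Poaceae,No,U
Briza minor,Briza,Poaceae,No,U;E
Brodiaea elegans,Brodiaea,Asparagaceae,Yes,U
Bromus hordeaceus,Bromus,Poaceae,No,U
Calandrinia menziesii,Calandrinia,Montiaceae,Yes,U;E
Capsella bursa-pastoris,Capsella,Brassicaceae,No,U
Castilleja attenuata,Castilleja,Orobanchaceae,Yes,U;E
Cotula coronopifolia,Cotula,Asteraceae,No,E;B
Deschampsia danthoniodes,Deschampsia,Poaceae,Yes,U
Dichelostemma capitatus,Dichelostemma,Asparagaceae,Yes,U
Downingia pulchella,Downingia,Campanulaceae,Yes,B
Eleocharis macrostachya,Eleocharis,Cyperaceae,Yes,E
Erodium botrys,Erodium,Geraniaceae,No,U
Erodium cicutarium,Erodium,Geraniaceae,No,U
Eryngium aristulatum,Eryngium,Apiaceae,Yes,B
Eschscholiza lobbii,Eschscholiza,Papaveraceae,Yes,U
Festuca perennis,Festuca,Poaceae,No,U
Hesperevax caulescens,Hesperevax,Asteraceae,Yes,B
Hordeum brachyantherum,Hordeum,Poaceae,No,U
Hypochaeris glabra,Hypochaeris,Asteraceae,No,B
Lasthenia fremontii,Lasthenia,Asteraceae,Yes,B
Lepidium nitidum,Lepidium,Brassicaceae,Yes,U;E
Limnanthes douglasii,Limnanthes,Limnanthaceae,Yes,E;B
Mimulus tricolor,Mimulus,Phrymaceae,Yes,B
Muilla maritima,Muilla,Asparagaceae,Yes,U
Plagiobothrys humistratus,Plagiobothrys,Boraginaceae,Yes,E;B
Plagiobothrys nothofulvus,Plagiobothrys,Boraginaceae,Yes,U
Pogogyne zizyphoroides,Pogogyne,Lamiaceae,Yes,B
Psilocarphus chilensis,Psilocarphus,Asteraceae,Yes,B
Psilocarphus tenellus,Psilocarphus,Asteraceae,Yes,B
Sanicula bipinnatifida,Sanicula,Apiaceae,Yes,U
Senecio vulgaris,Senecio,Asteraceae,No,U;E
Sidalcea calycosa,Sidalcea,Malvaceae,Yes,E;B
Trifolium depauparatum,Trifolium,Fabaceae,Yes,E
Trifolium microcephalum,Trifolium,Fabaceae,Yes,U
Trifolium variegatum,Trifolium,Fabaceae,Yes,U;E;B
Trifolium willdenovii,Trifolium,Fabaceae,Yes,U
Triphysaria eriantha,Triphysaria,Orobanchaceae,Yes,E
Triteleia hyacinthina,Triteleia,Asparagaceae,Yes,U
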