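{"wt_0.5": [-96.56698601341867, 7.04027515773439, 7.040352063008148, 148.25856710523303, 148.25853952682115, 4.568009030058767e-05, 5.627852439194852e-05, 1.190741924222947, 1.1491059178707632, 32.38441152768403, 0.0030971046182948275, 0.9042740913775575, 0.9042720301046789, 0.9042601169053606, 0.7732648389724862, 0.9042530581585635, 3.699855208037291e-05, 0.7677885646500419, 0.5906384408579421, 6.202575275886597e-05, 0.019443587655519977, 2.269732281615575e-06, 0.05519404651045724, 0.013379188680159311, 7.390710877324369e-05, 0.9968989239281173, 0.99851296337696, 9.289257543454206e-07, 3.236668791662377e-05, 0.0014537410124731752, 0.9999454309289405, 1.806499577327109e-07, 1.1814387564855323e-05, 4.257403516069975e-05, 0.9765872034562243, 5.846500051720816e-06, 0.0005097927763106432, 0.022897157267065888, 0.9999454309289239, 1.806499577327079e-07, 1.1814387564855128e-05, 4.257403516069905e-05, 0.9998376031157267, 1.017215893165511e-07, 3.5347081039032705e-06, 0.00015876045389258842, 0.9999454309288861, 1.8064995773270104e-07, 1.1814387564854678e-05, 4.257403516069741e-05, 0.998255775405016, 4.3584299922499576e-07, 3.797892972217759e-05, 0.0017058098231084577, 0.9999454309288812, 1.8064995773270017e-07, 1.1814387564854622e-05, 4.257403516069719e-05, 0.00023206856082704004, 0.0002906853353166256, 0.004041213301512415], "wt_1": [-97.17199304909057, 8.681267589975816, 8.68173397417711, 150.36972572311828, 150.36967158485265, 6.422432648548909e-05, 0.00016242360358164772, 1.4425965820748408, 1.131723822322078, 36.291100635188194, 0.0029135161774359363, 0.9125401553127773, 0.9125235020001163, 0.9124360188439175, 0.7901280869364282, 0.9123916778000177, 3.2981612942019035e-05, 0.7815505581699596, 0.5958724014929003, 5.8710814237709766e-05, 0.1419227662571848, 2.0789102252269195e-06, 0.21212279585231492, 0.07534864312403967, 6.907881665867881e-05, 0.9967092192389276, 0.9855380881568235, 9.026511071249648e-06, 0.0003144999454942596, 0.014138385387401642, 0.9995301858438125, 1.5504861882322354e-06, 0.00010230924454807767, 0.00036595442662037806, 0.9147169189767816, 2.1286186478828e-05, 0.001855513951396269, 0.08340628088669548, 0.9995301858438517, 1.5504861882322976e-06, 0.00010230924454808175, 0.0003659544266203926, 0.9984552357048487, 9.64415341847404e-07, 3.359363668417143e-05, 0.0015102062440837246, 0.9995301858438941, 1.5504861882323633e-06, 0.00010230924454808609, 0.00036595442662040826, 0.9933660560901765, 1.6560213418809235e-06, 0.00014433364209099316, 0.006487954248068251, 0.9995301858438582, 1.5504861882323078e-06, 0.00010230924454808243, 0.000365954426620395, 0.0021657786726195154, 0.002711032154305103, 0.01873204200964555], "wt_2": [-97.9459084708858, 9.952437989395168, 9.953224840830389, 153.28641419051897, 153.28633251515055, 6.666009723612572e-05, 0.00024414746193292887, 1.6298049089390332, 0.9313088186222443, 40.624166528482974, 0.0026944043794228344, 0.9221710410101485, 0.9221859908047084, 0.9219953890499174, 0.8106171966130553, 0.919314689755192, 2.8472360358488327e-05, 0.7791615609930678, 0.47635425750518184, 5.4713402974390276e-05, 0.27045374963945074, 0.00015771701969892506, 0.4624971578232224, 0.1617964526100947, 6.332191443218046e-05, 0.9964448390872618, 0.9454042297228422, 3.406094439908738e-05, 0.0011863059901747628, 0.053375403342768496, 0.9981188895613781, 8.376124688603988e-06, 0.0005558975343324768, 0.0013168367794878467, 0.8032205191184487, 5.705937671826812e-05, 0.004964170495758166, 0.19175825100933838, 0.9981188895615191, 8.376124688605185e-06, 0.0005558975343325562, 0.0013168367794880347, 0.9944197327013152, 3.4813507629949246e-06, 0.0001212449556193827, 0.005455540992684749, 0.9981188895614711, 8.376124688604782e-06, 0.0005558975343325296, 0.001316836779487971, 0.9834104339122375, 4.706917634908847e-06, 0.0004095717192310323, 0.0161752874510543, 0.9981188895614731, 8.376124688604796e-06, 0.0005558975343325306, 0.0013168367794879733, 0.004063241798782267, 0.005069926348729898, 0.0541784872639743], "ts1_0.5": [-96.31389745268719, 7.175119730335929, 7.175200211037234, 146.62503971040928, 146.62500901519803, 5.0152018017480625e-05, 5.6851089495377975e-05, 1.3686282909098433, 1.34044394511958, 30.879102148145424, 0.0031772846121127206, 0.9006133332415273, 0.9006119189111111, 0.9006036413491221, 0.7658954519103548, 0.9005986603146933, 3.882080219640827e-05, 0.7617263798947526, 0.5825059612938778, 9.667685125818165e-06, 0.01982296406677071, 2.3558089601208448e-06, 0.06756884698262838, 0.019911562967553302, 7.603050654454286e-05, 0.9969754674697705, 0.9989465538831072, 6.583317870688325e-07, 2.2938067986392313e-05, 0.0010298497167300223, 0.9999456353199891, 1.7844040400847116e-07, 1.1667908597380949e-05, 4.251833247145538e-05, 0.9869872394879053, 3.2503781827627766e-06, 0.00028345071643071307, 0.012726059417382312, 0.9999456353200187, 1.784404040084763e-07, 1.1667908597381286e-05, 4.251833247145661e-05, 0.9998306594873522, 1.0610140294765364e-07, 3.6872678075566858e-06, 0.00016554714221485233, 0.999945635319925, 1.784404040084597e-07, 1.16679085973802e-05, 4.251833247145266e-05, 0.9986428124415782, 3.392973935807997e-07, 2.956295890175298e-05, 0.0013272853028593711, 0.9999456353199728, 1.7844040400846817e-07, 1.1667908597380754e-05, 4.251833247145467e-05, 0.0001579489015569725, 0.0001978649233430402, 0.0049428792638303316], "ts1_1": [-96.76780510755758, 8.632540651441023, 8.63285651584689, 147.443301893065, 147.44324395996458, 6.201180797101641e-05, 0.00012472336355181716, 1.6375280548657618, 1.3797610265239406, 33.26948708366342, 0.0030349224608680423, 0.9070924682114421, 0.907077295452808, 0.9069929335807109, 0.7789162338440951, 0.9069459146271471, 3.561372026765591e-05, 0.7721895025009393, 0.5796648207504587, 9.27745972967565e-06, 0.08889801625647199, 2.2068046856452398e-06, 0.26356702442998503, 0.10379165856518995, 7.227452041830645e-05, 0.9968378615843444, 0.9910562239566335, 5.584476419128534e-06, 0.00019461231460716892, 0.008743579253143233, 0.999710570385524, 9.785988038064614e-07, 6.430952888819296e-05, 0.0002241414883543472, 0.9524198380741864, 1.1885104905599614e-05, 0.0010362377965166694, 0.04653203902495766, 0.9997105703851538, 9.785988038060982e-07, 6.430952888816908e-05, 0.00022414148835426403, 0.9985956031284858, 8.771509535829522e-07, 3.055900292040722e-05, 0.001372960717983182, 0.9997105703851716, 9.785988038061162e-07, 6.430952888817028e-05, 0.0002241414883542682, 0.9951909883142445, 1.2013567240999664e-06, 0.00010472087223315747, 0.004703089457943719, 0.9997105703852841, 9.785988038062263e-07, 6.43095288881775e-05, 0.00022414148835429336, 0.0013557469836067942, 0.0016978228909447781, 0.021246663177005295], "ts1_2": [-96.83404851533255, 10.9550834186371, 10.957201324827434, 148.25057848022686, 148.25047277048733, 0.0001269366890072701, 0.0007026038054607064, 3.431159843396244, 1.240723512137241, 36.791721993700904, 0.0030146904287031815, 0.9080047297517587, 0.9077364116531972, 0.9053683920490883, 0.7791739898924609, 0.8986031662354423, 3.516849733961214e-05, 0.7379586354384803, 0.41053571210785417, 9.232411464336367e-06, 0.7576495840014246, 0.0005598020116932992, 0.5351434152787568, 0.2821730756142637, 7.194170716465159e-05, 0.9968387384318268, 0.9573651537390029, 2.6673237950731734e-05, 0.0009294819543851955, 0.041678691068624034, 0.9787790396505226, 8.09515885745529e-05, 0.00606510911095244, 0.015074899649816847, 0.8379294585070806, 6.559884051991848e-05, 0.00569476341032202, 0.1563101792428553, 0.9787790396505446, 8.09515885745549e-05, 0.006065109110952591, 0.015074899649817201, 0.9938894485518462, 3.821035085402055e-06, 0.00013314494134523212, 0.005973585473682439, 0.9787790396504584, 8.095158857454775e-05, 0.006065109110952055, 0.015074899649815876, 0.9839639312772002, 6.002276104371237e-06, 0.0005213414136920937, 0.015508725033813271, 0.9787790396504853, 8.095158857455002e-05, 0.006065109110952226, 0.015074899649816304, 0.010241867599614972, 0.012858878616589691, 0.38326475648949304]}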