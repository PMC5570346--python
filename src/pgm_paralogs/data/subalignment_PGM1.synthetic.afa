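>PGM1
---WTLLSFRAPALVCLIMAPTTRVLLKGSTVTAPKSLRNN-------------------
------------------------------------GPQWPYPGASLNSLAEGEKAITND
FAQLIAHTSNGSVMPGQSRIESEENHCELEASIEAVIEYVDAPKSDEPSGSLTASHN--P
GGPLLLSAGSEELFKVLLAGGGAVTDFAHICPGNSVRNGKADSVGHHTAAVQEAKCSIQL
KNVCAGSMQEVNHGSCVALHYTARIIFQVIISEPTRWTPVENTGVVQTHGPNGFAPSHSA
LSVLLVVGGLRDAEGSVPIVH--------------LDWASAGADCGRRTSTRASTTEGAK
QDGDGDRLAMELPEPTIID----------------HLIKIKSALNKSRVFRGNYQIILVG
TGSGRPTRKWVGLIAPSVTPLNDRDTETGSLRAKGPSDQHLNATGEESFGVKI--DAKEE
PLCLRINEGSIGEERDSAEPIDSVNELRKRNQLR-----PQLVRIIYNIEKGDRGISANS
SIYNDYVLFRDNYLYLHTLFLLRVKSTAISRFLYMRNALHFAVLITPVVVEDEMGEGSDR
GSGTGKVGSKARLPKRQVLIAFEGFLTPVTFQEGNTEFNPECRTEQDETGVLDSKLKDF
>PGM1_rel1
---LTLLSFGAPALVGLIMEPTFRVLLKGSTSTIPKYLWNN-------------------
------------------------------------FPQRSAPFAYANSCAERERAFTND
QAQLAAHTSNGSVYPLVSRRASEENDCAQLLSIEAAIAMVDAPKSEINSGSLTASHN--P
GGPLLCSLGSEELFKVLLAGGGAVTQFAHDCPGNSRRVLEKDSVGHHVLAVQEEKCSFDL
KFVCDRSMQEVVWFSLATAHVTLVIEFQVFFSGPTRLTPVENTGVIQTHGMNGSGPSHFA
LSVLLVVFGLPHAEGSVPIVH--------------LDWASAGAQCGRRVSFRASFTEGAK
CDGDGDRLAVITPEPSIVD----------------HLIKRKSELNKCKVIIGVYLIELVG
TGCAIPTRKWVGLTLPSNTQLIDGDSETGVLRALGPSDQAENATGEESFGVKI--DAKAE
PLALRFNEGSPMAPRGSDEPTDSNNLLRKRNQLR-----PQHIVIDYNTEKGDRAISANS
TEYNGYVRLRSPYLYLHTGILLQVKSTEISIQLAERKALHFRVLISPNNVEDEMGEGSDR
GSGTGKVGSKARLPKRQDLIAFEATLTPPTAQAGNEYTAPECRKEDDETLNLFTKKKDI
>PGM1_rel2
---WTLLSFIAPELVLLRYEPTTRVLLKGSFITAPRSSRFN-------------------
------------------------------------RPQHPYPEASLNSLIEGERAGTND
QAQLIEHTSNGGVMPGRSRIESEENHCILEAKIAEIIHYVDLPKSERPSFSLTASHN--P
GGHLLLSAGVAGLFKVLAAGGFAVTDFAEELPENSVQNGKEDSIQAHTAYVQITKSSIQL
KNSEPGYMQELNVGSCVALHYTARGKFVVIRSDPTRWVPVENTGVVQTHGPAGFLPSHLA
LSVLLVWGGSRQHEGSVPIVH--------------LDGASAGLDCPRGTSTWASRPEGRW
QDGDGDRLHMAHPAPLVTK----------------ALRKIKSELQKVRVFRGNYQETLNG
TGSGRPTRKGTGLIAPSVTPLNDIDLETGSVAAKGSIDQALNLTGEESFGFKA--DAKAE
PACLRNNEGSIGEEGDQGDAVDSVNELRKRFQGR-----PQCVRIEYNIEWGDFGISLNY
SIYNVVVLKRWNYAYAHTWGLLRVRQTARSRIPYMINALHGAVAQTPILVRDGFGAGKGR
GSGTGKVGSKARLPKKQVLEHFEGGLTPYTFCGCNKAMNSLLKTEQDESGWLKSKLKDT
>PGM1_rel3
---WFALSFGLPAQVLVIWFPTTRVLLRGPTITAPKSLRNN-------------------
------------------------------------GPQKLYPGFSLPSLAERETAITND
FAQGEAATCPGSTMDGISGIESEHNHCELEAPRQAVFIYVDAPKSDYPGGSLTASHN--P
GGPQDCSEGSREGTVVLLADGGEVFDVADFLPCVSVRNGKPLSVGHHTLACQEADLSIQL
KNTGAGSQFEVNAESQVALHYTARIIFFVIRSEPTKWTPVEDTGVVQTHGPSCFAPSPTA
LSLLLVVGVLRCAEFSVPFIH--------------LDKASLGADLGRRTSTRASFTAGEK
QDGDGDRLGMALPEPTFID----------------PLIRIKSALNKPIVFRGVYQEIAVG
TGSGKPTRKAVGLFASSNTPLNDRDVETGSMRAKGPSDFDSNETGEESFGVKI--DAKIE
PLCKRINCGSIGSKRDPAEPIDSVNELRKRWRLR-----PVLIRVIYPIEKGDFGILANT
SSQNDYGLIRDASLYLATLFLTRVRSTAESRLLYGRVALLDAVLITPCQVEDEMGEESDR
GSGTGKVGSKARLPKRQIRFATEGFLFPVTAQIGNTEFRIECKTAQAESQILPYKLKEE
>PGM1_rel4
---WRLLFNWGPCLSCLITAPTTRSALKHTIVTEPKSLRNN-------------------
------------------------------------GPQAPYPGAELNSLAEGKRAITND
FLRLEEHTVNRSVMPGLSSFESAANHCILAASVEAVIAYVNAGKSDEHIGSLTASHN--P
GGPLLLSAGSIALERVKQAGGGAVTDFAHICPLNYVRNGRADSFGHHHCANTETDLSIFL
KNVCAASMFESVHRSCVALHYTAGVFCAVVISEPTKWTPVEVTGVVQTAGENGFEPSCSA
LSVDLNIGGLRGAAGSIPIVH--------------LDHPSTGADIRGRTSTRHSTGIGAR
DDGDGDRLGFELSEPTVIR----------------ALEKIKSHINKMIVFIGNYQIILGG
LGSGRPTRKWVGLELPSVTDLNDRDTYGGSLRAKGPVDQHLGAFGEESFGVLI--DAKAE
PLVLRINLGSIGEERDSEIPIDSVGELRKREQLR-----IQLVRFIWKSENFDRAESAVS
SEYNDYVLFRDNSLSLHTLFCLKVKSTYISVFAYMRNAAHGAVLETPSGVADEGREASDR
GSGTGKVGSKARLTRRYVLFLQEGVVTPTTAQEGVTEFNSEDIFELGRTGVLDYKLKDF
>PGM1_rel5
---LSLASVFAPALVALQMHPTSKVALKGSSNTHPASLIVN-------------------
------------------------------------GAQWPYPKADLNSCYAGTKAISPD
FADLIAETSNGSVNPGQTRLESEENECELAASSELINEYNDAPKSDMPSRSATASHN--P
GGQALVYPGSEFLMKVLLAGAGAVTQFAESCPGKSVRNKGADSVGHHTEHVQAARCSRDL
DNVCTGRMQDQFHTSQCPLHYTERRIFQVNSPEPTWWTWTEFTGVVRTHGPNGFAPSASA
LSVLLVVQGLIMAEGSVPIVH--------------LDWLSAGADCGKKTTTWASTTESER
QDGDGDRTAMELPEPTIID----------------HLIIIDSALNKSRVFRGVSQIILLG
TALGRPTLKWNGLIAPSVTPLNDISAETGSLGAKGITELVANATGEESFGVRV--DAKKE
PLYLKINEGSRGAERDSLEPFQSINELRKRNLLR-----PLLVRVIYGIEKGDEGISCNS
SIYNDYVCFRINYAYLHTLTRLRVGSVAISRFLYFRNALHFAVLITHVVVFGEVGARSER
GSGTGKVGSKARLPKRDVLIAFAGFLTPLFFQTGNTAGPPECATEQDETGFLDSKLREF
>PGM1_rel6
---AFLLYGYRPFQVCLEMANTTKVLLRGSTVSAPKSLRMN-------------------
------------------------------------GPQWPYPGPTLISLAEGEVAITND
IAQLIHHTSKYSVMRGFSIIISEENHEILIAYIRAVIAYVDHPKNDEDSDVLTASHN--P
GGPGLLSAGTEELFKFLRAGGGAVTANAHICPGDPVIKGKLDSQGWWTAPVQEAKCSIQA
KNVCLGSMQENNPGSLVALHYTARIIGQVVISEPTKQTPIENTGVVQTHGPNRDEPPHGA
WICLLVVHGVGDYEGSVVINH--------------LDWAVYGEQLGFITSTGEPTTIGAK
CDGDGDRLAMLLPEPFFSD----------------HDFKIKSELNKSRVGRGFYQIILLG
TFSRGPTRKWVTLVLPTTTNVNDWDTAFGTWIAKGPSDQELRATGEESFGFNY--PAFLE
PLCLRINEGSIGEARDTGEPDDSVNALKDRATLR-----PQLVGIKYNQEKGDGGISLGY
TIYNDSQLFIDAYLFKALLGCLRVKSFAITWFLYMANALHVENAIAPVVVADEMFEFSDR
GSGTGKVGSKARLPKKQSLILMAGFLVPVLFQEGNTFFNPECRTECDETHRCDWKLKDF
>PGM1_rel7
---WTLLSFRAPALVNLIMDPTTRVLLRGSTDSAPKSCRSN-------------------
------------------------------------GPQRPYPLASLNSCEIGEKAVTND
GAQEIAHTGNGSPMPGQSGIEVAENHCELEAYIECVIEIVCEPVTDEPSGSLTASHN--P
GGPQLLSPGSEELGKVLLAGQGKLLDGAWILPGNSVGNFKLDSVGHHTAAVLEFKGSITL
DNVCANSMYEVNAGSCVALHSTARRRFFVIFYGPTRLTPVENTGVVQTHGPNGFAPPWSA
LSILLVVGGLFDAEGSLPIVH--------------WDQASEGKAPGRRTSTYASTEEACR
QDGDGDRLAMELPEPEARD----------------HLVKIKTCLNVSRVFGLNLQQILVG
TLSGRPTRKWVGLIAPSVIPLNDRTTDLGSLHPKFPSEQHLNADGEESFGCKI--DAKIE
PLCLRINEGSIRDARDSAEPREYVGELKKGRQLR-----WQAVRIHVNIIKGDVGIPADT
SEYNDYVLTKDNYWYLPFLNQLRKKSTEISRFLYMPVALAFHVQETPVIMWDEMGHGYDR
GSGTGKVGSKARLPKRLVCIAFCGGLSPVTFQGGNGEFAPELRSIQDETGVLEDKLKDT
>PGM1_rel8
---WRLLSKRAPHLVCLAMQPTTRVLLNFSTVDAPISLIMN-------------------
------------------------------------GPQWSYPFGSLNSLAEGEKAEFND
ILQLEAHTSNRSEMPGQSRVEAAENHCAWDPSFDAISEYVDALVSDEPGGSITASHN--P
GGPLLLSRGYEYLFRVLLATEGEVTDTAAICPGNSVRNLKAGNVGHHTAAVQIEAVTIFL
KNTCLGSMQEVNHGSGVALHYTARIIQLVIVSESTRPTPVETTAIVQATGVNGTAPSHSA
LSVLLVVGGLKQAEGSVPIVH--------------LDLLRALADCGKRLSTRASTSIGGK
QDGDGDRLADILPEPQIIQ----------------CLIKIYSAQNKIKMFGGNYQEIAVG
TGSRRPTIKWVGEIAPVVTPLIDRDTETGSLGHKDPTDNHLVASGEESFGVQI--EAEEE
PLIKRINEGSIGEEGKSAIPFDSVNELICRVQLR-----PQLCRIISNTEKGDAMISINT
SIYNDYVLFGDNSLYLHTCGLLRWASTGILRGLYFKNAAHFEVLITSCVPEDFMGEGSDR
GSGTGKVGSKARLPRRQVLIWTDHFLTSVTEQEGNTEFNPEWFTEYDEFGVKDSKTKDF
>PGM1_rel9
---WTFLSTGAPALVAAIMASTTRVLLKGSTVTLPKLFERN-------------------
------------------------------------GPQWPYEAASLRSLAETEDAITND
GAQCCEHNRNGSVMPGQSCQESAANACIWEASIEGVREYQDAPGSDIPSGSATASHN--P
GGPLGNSAWSEELVRVLLAAGGAVTDFAHIFPMNSVRNGKEDTVGHHVALVQEHKCVIWL
KNVCLGSMQAVNAQSCSALHYTAIIVFQVIFSSHTRWTPRENTGVIQDHGPNGFAPSHSA
LTVFLVVCGLHDYAGSVEIVH--------------ADWKLAGAFCGDETSFRASSTAGAK
QDGDGDRLGPAKPEPSVID----------------ALEKIKTLFNKSRVFTGCYQRVQVG
HGSGRPTRKHVGKIAPSVTPLVDRITETGSLQAKGPSDQHRNATGEESFGVRR--NGTAE
PLCLRINDGTFLEERISAEPIKSVVEGRKRNQLR-----PQLIKEIYVVEKSPRGTSMVS
SIYNDVVLFRVVALYLHTQFQLAVKSVAISRFLYMRRALARNVLIGPVVVIDEMGEGSDR
GSGTGKVGSKARLPKRQRLIGTEGFLFPVTFLERVTDTNPELRYEVICIGNKDSKLKQQ
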