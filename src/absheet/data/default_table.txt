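# absheet square-well parameter table
VERSION 1
HB WIDTH 5.0
HB DEPTH 1.0
HB AUXMIN 4.5
GEOM SC_DIAMETER A 2.7
GEOM SC_DIAMETER C 3.6
GEOM SC_DIAMETER D 3.6
GEOM SC_DIAMETER E 3.9
GEOM SC_DIAMETER F 4.5
GEOM SC_DIAMETER G 0.0
GEOM SC_DIAMETER H 4.4
GEOM SC_DIAMETER I 4.4
GEOM SC_DIAMETER K 4.4
GEOM SC_DIAMETER L 4.4
GEOM SC_DIAMETER M 4.3
GEOM SC_DIAMETER N 3.8
GEOM SC_DIAMETER P 4.0
GEOM SC_DIAMETER Q 4.1
GEOM SC_DIAMETER R 4.6
GEOM SC_DIAMETER S 3.2
GEOM SC_DIAMETER T 3.7
GEOM SC_DIAMETER V 4.0
GEOM SC_DIAMETER W 5.0
GEOM SC_DIAMETER Y 4.7
GEOM SC_OFFSET A 1.6
GEOM SC_OFFSET C 2.1
GEOM SC_OFFSET D 2.1
GEOM SC_OFFSET E 2.4
GEOM SC_OFFSET F 2.5
GEOM SC_OFFSET G 0.0
GEOM SC_OFFSET H 2.6
GEOM SC_OFFSET I 2.3
GEOM SC_OFFSET K 2.6
GEOM SC_OFFSET L 2.3
GEOM SC_OFFSET M 2.5
GEOM SC_OFFSET N 2.2
GEOM SC_OFFSET P 1.9
GEOM SC_OFFSET Q 2.5
GEOM SC_OFFSET R 3.2
GEOM SC_OFFSET S 1.7
GEOM SC_OFFSET T 2.0
GEOM SC_OFFSET V 1.95
GEOM SC_OFFSET W 2.9
GEOM SC_OFFSET Y 2.7
GEOM BACKBONE_DIAMETER 3.3
GEOM BOND_TOLERANCE 0.02
GEOM CA_SPACING 3.8
PAIR A A 4.7000 0.0567
PAIR A C 5.1500 0.0756
PAIR A D 5.1500 0.0000
PAIR A E 5.3000 0.0000
PAIR A F 5.6000 0.1134
PAIR A G 3.3500 0.0000
PAIR A H 5.5500 0.0000
PAIR A I 5.5500 0.1260
PAIR A K 5.5500 0.0000
PAIR A L 5.5500 0.1197
PAIR A M 5.5000 0.0819
PAIR A N 5.2500 0.0000
PAIR A P 5.3500 0.0000
PAIR A Q 5.4000 0.0000
PAIR A R 5.6500 0.0000
PAIR A S 4.9500 0.0000
PAIR A T 5.2000 0.0000
PAIR A V 5.3500 0.1197
PAIR A W 5.8500 0.0630
PAIR A Y 5.7000 0.0378
PAIR C C 5.6000 0.1008
PAIR C D 5.6000 0.0000
PAIR C E 5.7500 0.0000
PAIR C F 6.0500 0.1512
PAIR C G 3.8000 0.0000
PAIR C H 6.0000 0.0000
PAIR C I 6.0000 0.1680
PAIR C K 6.0000 0.0000
PAIR C L 6.0000 0.1596
PAIR C M 5.9500 0.1092
PAIR C N 5.7000 0.0000
PAIR C P 5.8000 0.0000
PAIR C Q 5.8500 0.0000
PAIR C R 6.1000 0.0000
PAIR C S 5.4000 0.0000
PAIR C T 5.6500 0.0000
PAIR C V 5.8000 0.1596
PAIR C W 6.3000 0.0840
PAIR C Y 6.1500 0.0504
PAIR D D 5.6000 0.0000
PAIR D E 5.7500 0.0000
PAIR D F 6.0500 0.0000
PAIR D G 3.8000 0.0000
PAIR D H 6.0000 0.0000
PAIR D I 6.0000 0.0000
PAIR D K 6.0000 0.2500
PAIR D L 6.0000 0.0000
PAIR D M 5.9500 0.0000
PAIR D N 5.7000 0.0000
PAIR D P 5.8000 0.0000
PAIR D Q 5.8500 0.0000
PAIR D R 6.1000 0.2500
PAIR D S 5.4000 0.0000
PAIR D T 5.6500 0.0000
PAIR D V 5.8000 0.0000
PAIR D W 6.3000 0.0000
PAIR D Y 6.1500 0.0000
PAIR E E 5.9000 0.0000
PAIR E F 6.2000 0.0000
PAIR E G 3.9500 0.0000
PAIR E H 6.1500 0.0000
PAIR E I 6.1500 0.0000
PAIR E K 6.1500 0.2500
PAIR E L 6.1500 0.0000
PAIR E M 6.1000 0.0000
PAIR E N 5.8500 0.0000
PAIR E P 5.9500 0.0000
PAIR E Q 6.0000 0.0000
PAIR E R 6.2500 0.2500
PAIR E S 5.5500 0.0000
PAIR E T 5.8000 0.0000
PAIR E V 5.9500 0.0000
PAIR E W 6.4500 0.0000
PAIR E Y 6.3000 0.0000
PAIR F F 6.5000 0.2268
PAIR F G 4.2500 0.0000
PAIR F H 6.4500 0.0000
PAIR F I 6.4500 0.2520
PAIR F K 6.4500 0.0000
PAIR F L 6.4500 0.2394
PAIR F M 6.4000 0.1638
PAIR F N 6.1500 0.0000
PAIR F P 6.2500 0.0000
PAIR F Q 6.3000 0.0000
PAIR F R 6.5500 0.0000
PAIR F S 5.8500 0.0000
PAIR F T 6.1000 0.0000
PAIR F V 6.2500 0.2394
PAIR F W 6.7500 0.1260
PAIR F Y 6.6000 0.0756
PAIR G G 2.0000 0.0000
PAIR G H 4.2000 0.0000
PAIR G I 4.2000 0.0000
PAIR G K 4.2000 0.0000
PAIR G L 4.2000 0.0000
PAIR G M 4.1500 0.0000
PAIR G N 3.9000 0.0000
PAIR G P 4.0000 0.0000
PAIR G Q 4.0500 0.0000
PAIR G R 4.3000 0.0000
PAIR G S 3.6000 0.0000
PAIR G T 3.8500 0.0000
PAIR G V 4.0000 0.0000
PAIR G W 4.5000 0.0000
PAIR G Y 4.3500 0.0000
PAIR H H 6.4000 0.0000
PAIR H I 6.4000 0.0000
PAIR H K 6.4000 0.0000
PAIR H L 6.4000 0.0000
PAIR H M 6.3500 0.0000
PAIR H N 6.1000 0.0000
PAIR H P 6.2000 0.0000
PAIR H Q 6.2500 0.0000
PAIR H R 6.5000 0.0000
PAIR H S 5.8000 0.0000
PAIR H T 6.0500 0.0000
PAIR H V 6.2000 0.0000
PAIR H W 6.7000 0.0000
PAIR H Y 6.5500 0.0000
PAIR I I 6.4000 0.2800
PAIR I K 6.4000 0.0000
PAIR I L 6.4000 0.2660
PAIR I M 6.3500 0.1820
PAIR I N 6.1000 0.0000
PAIR I P 6.2000 0.0000
PAIR I Q 6.2500 0.0000
PAIR I R 6.5000 0.0000
PAIR I S 5.8000 0.0000
PAIR I T 6.0500 0.0000
PAIR I V 6.2000 0.2660
PAIR I W 6.7000 0.1400
PAIR I Y 6.5500 0.0840
PAIR K K 6.4000 0.0000
PAIR K L 6.4000 0.0000
PAIR K M 6.3500 0.0000
PAIR K N 6.1000 0.0000
PAIR K P 6.2000 0.0000
PAIR K Q 6.2500 0.0000
PAIR K R 6.5000 0.0000
PAIR K S 5.8000 0.0000
PAIR K T 6.0500 0.0000
PAIR K V 6.2000 0.0000
PAIR K W 6.7000 0.0000
PAIR K Y 6.5500 0.0000
PAIR L L 6.4000 0.2527
PAIR L M 6.3500 0.1729
PAIR L N 6.1000 0.0000
PAIR L P 6.2000 0.0000
PAIR L Q 6.2500 0.0000
PAIR L R 6.5000 0.0000
PAIR L S 5.8000 0.0000
PAIR L T 6.0500 0.0000
PAIR L V 6.2000 0.2527
PAIR L W 6.7000 0.1330
PAIR L Y 6.5500 0.0798
PAIR M M 6.3000 0.1183
PAIR M N 6.0500 0.0000
PAIR M P 6.1500 0.0000
PAIR M Q 6.2000 0.0000
PAIR M R 6.4500 0.0000
PAIR M S 5.7500 0.0000
PAIR M T 6.0000 0.0000
PAIR M V 6.1500 0.1729
PAIR M W 6.6500 0.0910
PAIR M Y 6.5000 0.0546
PAIR N N 5.8000 0.0000
PAIR N P 5.9000 0.0000
PAIR N Q 5.9500 0.0000
PAIR N R 6.2000 0.0000
PAIR N S 5.5000 0.0000
PAIR N T 5.7500 0.0000
PAIR N V 5.9000 0.0000
PAIR N W 6.4000 0.0000
PAIR N Y 6.2500 0.0000
PAIR P P 6.0000 0.0000
PAIR P Q 6.0500 0.0000
PAIR P R 6.3000 0.0000
PAIR P S 5.6000 0.0000
PAIR P T 5.8500 0.0000
PAIR P V 6.0000 0.0000
PAIR P W 6.5000 0.0000
PAIR P Y 6.3500 0.0000
PAIR Q Q 6.1000 0.0000
PAIR Q R 6.3500 0.0000
PAIR Q S 5.6500 0.0000
PAIR Q T 5.9000 0.0000
PAIR Q V 6.0500 0.0000
PAIR Q W 6.5500 0.0000
PAIR Q Y 6.4000 0.0000
PAIR R R 6.6000 0.0000
PAIR R S 5.9000 0.0000
PAIR R T 6.1500 0.0000
PAIR R V 6.3000 0.0000
PAIR R W 6.8000 0.0000
PAIR R Y 6.6500 0.0000
PAIR S S 5.2000 0.0000
PAIR S T 5.4500 0.0000
PAIR S V 5.6000 0.0000
PAIR S W 6.1000 0.0000
PAIR S Y 5.9500 0.0000
PAIR T T 5.7000 0.0000
PAIR T V 5.8500 0.0000
PAIR T W 6.3500 0.0000
PAIR T Y 6.2000 0.0000
PAIR V V 6.0000 0.2527
PAIR V W 6.5000 0.1330
PAIR V Y 6.3500 0.0798
PAIR W W 7.0000 0.0700
PAIR W Y 6.8500 0.0420
PAIR Y Y 6.7000 0.0252
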