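# Synthetic stand-in for the human mGluR1 reference (900 aa).
# Arg78/Lys409 and seven hydrophobic transmembrane helices are planted;
# the background is random. Override with a real sequence if available.
name: mGluR-mGluR1
description: synthetic mGluR1-like reference with planted glutamate-binding sites and 7TM region
sites:
  "78": 78
  "409": 409
tm_span: [580, 816]
sequence: |
  RTVANTFVPKLASGRLGKANLKRKTQLYFDVESISYWSEYNQKPAQGTATEKYALDFSCT
  DINEGFELMSEACLTMKRIEEVNREKQFFHTEKLAELVSIDQALGMLGEAVAADNSNEAY
  ETVPQISFSLMGDFASAKKRKPLFFDYELRVMILACVRNLSTTPELSNRIEALGTEMLEI
  GCRADRNRGCAAVCAKLGPVGGLCNGFANSELALADHLRISFGISQNVTTIAPSVASEMW
  QVARIPYTVHGLFWKYGSVRFWWTQGLVQMPNTLVTVDTTVMGLNVPEYPEYEEAFRAMV
  APCTADVLNAGHLFNEAVGFQNDAFVRNSKVGHQSDGMYSRTSILHAEYKRLKSLDVEPF
  YSGAMAAALSAEGWKGYFFPLIVLGRDVVAAFDMDGECSEYDWNEVATKLVRGLMEQYAV
  NCPPLADDWISYGYFKIHEQIGQAVLETITNNCTSEYTGKVFDKWLIPIKASVTSIPIRA
  ETIRALQKEHNGLLRTPNRNGCCKRDYRDYSHVEKDICPDTWSTEAYLASEVVKYGQPLA
  EAEIGLAVDRKFEYNNTILSIWDINCKKGAHQVLTFRIVMVMLFFVILLMVALLVLLVIL
  DNSDKGGRGKTQNSDILVFVFIIALVVVIFIVLLVLDPQTQGQESEGSPSKVFFLVMVLA
  AAILFLIVFVLVDQGDRERDGNNSGKKILIIVIIAIIMVFVIALLIIVQQSGQRKRQTND
  EDRVVVLILVLIALALMIFIIALMPGRGNEGGEGQTKKGVILALLLALMLFLFIILALLI
  QDEGKDSEDGRGTKDILLALVLFVVFLIFLVMFAIVLNSSPMTHEWRVDESRGMETELER
  QSEETYLRQSGYGVMQLSQEGGVKLVGFNTEIANSFASKVYGRGGLQEAPQFQTCRSCDL
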