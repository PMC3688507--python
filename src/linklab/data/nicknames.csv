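nickname,canonical
BILL,WILLIAM
BILLY,WILLIAM
WILL,WILLIAM
WILLIE,WILLIAM
BOB,ROBERT
BOBBY,ROBERT
ROB,ROBERT
ROBBIE,ROBERT
BERT,ALBERT
BERTIE,ALBERT
JIM,JAMES
JIMMY,JAMES
JAMIE,JAMES
TOM,THOMAS
TOMMY,THOMAS
MIKE,MICHAEL
MICK,MICHAEL
MICKEY,MICHAEL
DAVE,DAVID
DAVEY,DAVID
STEVE,STEPHEN
STEVIE,STEPHEN
RICK,RICHARD
RICKY,RICHARD
DICK,RICHARD
RICH,RICHARD
TONY,ANTHONY
FRED,FREDERICK
FREDDIE,FREDERICK
HARRY,HENRY
HAL,HENRY
JACK,JOHN
JOHNNY,JOHN
JON,JOHN
ALEX,ALEXANDER
SANDY,ALEXANDER
SAM,SAMUEL
SAMMY,SAMUEL
BEN,BENJAMIN
BENNY,BENJAMIN
DAN,DANIEL
DANNY,DANIEL
NICK,NICHOLAS
NICKY,NICHOLAS
TED,EDWARD
TEDDY,EDWARD
ED,EDWARD
EDDIE,EDWARD
NED,EDWARD
RON,RONALD
RONNIE,RONALD
DON,DONALD
DONNY,DONALD
KEN,KENNETH
KENNY,KENNETH
GEOFF,GEOFFREY
JEFF,JEFFREY
GREG,GREGORY
PHIL,PHILLIP
PAT,PATRICK
PADDY,PATRICK
MATT,MATTHEW
JOSH,JOSHUA
JAKE,JACOB
NATE,NATHAN
ZACH,ZACHARY
CHRIS,CHRISTOPHER
TOPHER,CHRISTOPHER
ANDY,ANDREW
DREW,ANDREW
STAN,STANLEY
LEN,LEONARD
GERRY,GERALD
TERRY,TERENCE
LARRY,LAWRENCE
BARRY-JNR,BARRY
GUS,ANGUS
DOUG,DOUGLAS
MAX,MAXWELL
RAY,RAYMOND
BRAD,BRADLEY
LIZ,ELIZABETH
LIZZIE,ELIZABETH
BETH,ELIZABETH
BETSY,ELIZABETH
BETTY,ELIZABETH
ELIZA,ELIZABETH
LIBBY,ELIZABETH
MAGGIE,MARGARET
MEG,MARGARET
PEGGY,MARGARET
PEG,MARGARET
MARGE,MARGARET
MADGE,MARGARET
SUE,SUSAN
SUSIE,SUSAN
SUZIE,SUSAN
PATTY,PATRICIA
TRICIA,PATRICIA
TRISH,PATRICIA
JENNY,JENNIFER
JEN,JENNIFER
BECKY,REBECCA
BECCA,REBECCA
JESS,JESSICA
JESSIE,JESSICA
MANDY,AMANDA
NIKKI,NICOLE
TINA,CHRISTINA
CHRISSY,CHRISTINE
VICKY,VICTORIA
DEBBIE,DEBORAH
DEB,DEBORAH
CINDY,CYNTHIA
KATE,KATHERINE
KATIE,KATHERINE
KATHY,KATHLEEN
KATH,KATHLEEN
CATHY,CATHERINE
CATH,CATHERINE
KIT,CATHERINE
MOLLY,MARY
POLLY,MARY
FRAN,FRANCES
FRANNIE,FRANCES
JO,JOSEPHINE
JOSIE,JOSEPHINE
DOT,DOROTHY
DOTTY,DOROTHY
DOLLY,DOROTHY
SALLY,SARAH
SADIE,SARAH
ELLIE,ELEANOR
NELL,ELEANOR
NORA,ELEANOR
EM,EMILY
MILLIE,EMILY
EMMY,EMMA
ABBY,ABIGAIL
GAIL,ABIGAIL
SOPH,SOPHIE
GRACIE,GRACE
FLO,FLORENCE
FLOSSIE,FLORENCE
WINNIE,WINIFRED
GWEN,GWENDOLYN
SYL,SYLVIA
PAM,PAMELA
BARB,BARBARA
BABS,BARBARA
LINDY,LINDA
MICHELLE-M,MICHELLE
SHELLEY,MICHELLE
CAZ,CAROL
CAROLINE,CAROL
RONA,VERONICA
HAYLS,HAYLEY
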